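G_SOL 1.4958399092332189
G_TA 2.2365792939159648
loff_TA 0.5356385136173476
GS_TA 1.0138743798603316
G_GAS 1.0142261853480539
G_VAS 1.9890126029852013
loff_knee 0.7804046368499109
k_knee 7.6548007449338051
S0_VAS 0.37608518135055419
kp_trunk 2.8385799000176304
kd_trunk 0.64146107601302582
theta_ref 0.065939602464151342
kHAM_tr 0.40639323001013011
kHFL_tr 0.022626820877326564
dS_HFL 0.18186242776445841
dS_GLU 0.4511700237333508
S0_HFL_sw 0.28121873376618262
G_HFL 0.38599380732203525
loff_HFL 1.0185740718464162
GHAM_HFL 8.5970707469479031
loff_HAM 1.0333687396270035
k_lean 1.1359106621776125
GHAM_sw 0.23339902051485972
kGLU_HAM 0.74689702162596094
G_BFSH 3.5599673199216975
loff_BFSH 1.1666503737270548
GVAS_lsw 0.55705661638423942
loff_VAS_lsw 0.77969295921261217
GGAS_lsw 0.10953435582105872
S0_GLU 0.27518967499680569
S0_HAM 0.016947498857191906
kDS_VAS 1.6152779054906818
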