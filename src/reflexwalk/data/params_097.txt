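G_SOL 1.0996460183809336
G_TA 1.9610233014667018
loff_TA 0.59148005387749891
GS_TA 0.79756193599851544
G_GAS 1.0166500509578609
G_VAS 2.2741404000205776
loff_knee 0.84224771314202762
k_knee 4.6453222932048908
S0_VAS 0.29896342004291432
kp_trunk 2.9814630007736977
kd_trunk 0.65976101130755749
theta_ref 0.0036365730767792953
kHAM_tr 0.39488421297973514
kHFL_tr 0.47308686751132228
dS_HFL 0.033424212660600382
dS_GLU 0.42869012451873884
S0_HFL_sw 0.18393670290596106
G_HFL 0.75098188395888044
loff_HFL 1.0627750878103042
GHAM_HFL 7.2597821410058394
loff_HAM 1.0914914153940456
k_lean 1.2426617216086828
GHAM_sw 0.32750079002594834
kGLU_HAM 0.42248173625368091
G_BFSH 4.858525398598065
loff_BFSH 1.2377139336579708
GVAS_lsw 0.21886074001756356
loff_VAS_lsw 0.77421818666203635
GGAS_lsw 0.36476315304236101
S0_GLU 0.26347934497175129
S0_HAM 0.01
kDS_VAS 2.5940338993851562
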