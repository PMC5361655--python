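G_SOL 1.5081451372766395
G_TA 1.0764385310162563
loff_TA 0.69108407396830374
GS_TA 0.72139908734459479
G_GAS 1.1629731931759171
G_VAS 1.1481848636666343
loff_knee 0.77803176593242518
k_knee 9.1191313731541737
S0_VAS 0.077039148085858017
kp_trunk 2.1382552834727626
kd_trunk 0.84271397475826704
theta_ref 0.021442314458724056
kHAM_tr 1.9279175958249002
kHFL_tr 1.5394479776136112
dS_HFL 0.39848666296907531
dS_GLU 0.79571933134317163
S0_HFL_sw 0.0123184777239971
G_HFL 0.020466646944243473
loff_HFL 0.35986481812744264
GHAM_HFL 3.2161528934188341
loff_HAM 0.93188797423403158
k_lean 2.9688091521737632
GHAM_sw 0
kGLU_HAM 1.3404554175139265
G_BFSH 1.9876743250616489
loff_BFSH 1.2150335482417178
GVAS_lsw 0.1105999166411816
loff_VAS_lsw 0.96588370908412136
GGAS_lsw 1.858249980858343
S0_GLU 0.041211029825587525
S0_HAM 0.01412869482361903
kDS_VAS 1.830437539165223
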