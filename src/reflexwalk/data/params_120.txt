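G_SOL 1.6000000000000001
G_TA 2.3413825969100661
loff_TA 0.46884375803342654
GS_TA 1.2679314399832253
G_GAS 1.0338151954626582
G_VAS 1.9736380850241269
loff_knee 0.70917574534686301
k_knee 8.6796997972134537
S0_VAS 0.32124157249783608
kp_trunk 2.0480227976885157
kd_trunk 0.58810561992960342
theta_ref 0.090428651306002111
kHAM_tr 0.69811111852806307
kHFL_tr 0
dS_HFL 0.34433206058927812
dS_GLU 0.47582041116239471
S0_HFL_sw 0.29591622921337934
G_HFL 1.1573131733161117
loff_HFL 0.95332068079700183
GHAM_HFL 8.6651425236498358
loff_HAM 1.0444786887882334
k_lean 1.3634669669345292
GHAM_sw 0.18635879461976862
kGLU_HAM 0.77193286552175899
G_BFSH 4.0333747631778083
loff_BFSH 1.2166717196188248
GVAS_lsw 0.59914824140530909
loff_VAS_lsw 0.80753127688684911
GGAS_lsw 0.56232358621475975
S0_GLU 0.27747461665583084
S0_HAM 0.021360668414510231
kDS_VAS 2.0383266168372631
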