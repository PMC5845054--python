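# A priori tumor-organ parameters (xenograft, HT-29): continuous
# endothelium pore geometry, tumor-specific hydraulic conductivity and
# specific blood flow.  Lymph/recirculation factors from the fitted
# tumor row of the flow-factor table.
volume_ml: 0.2
specific_blood_flow_ml_min_g: 0.21
f_vas: 0.05
f_int: 0.45
Lp: 1.6e-3
alpha_L: 0.05
r_S: 4.5
r_L: 25.0
f_lymph: 3.65e-3
f_Jiso: 0.281
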