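# Domain antibody dAb2, 10 mg/kg IV bolus, mouse (renal filtration f_GFR = 0.24)
species: mouse
compound: domain_antibody
doses: [{time_min: 0.0, mg_per_kg: 10.0}]
t_end_min: 4320.0       # 3 days
n_points: 400
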