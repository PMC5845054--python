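# 7E3 antibody, single 8 mg/kg IV bolus, wild-type mouse
species: mouse
compound: antibody_7e3
doses: [{time_min: 0.0, mg_per_kg: 8.0}]
t_end_min: 40320.0      # 28 days
n_points: 400
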