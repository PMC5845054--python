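# CDA1, 10 mg/kg 60-min IV infusion, healthy adult
species: human
compound: cda1
doses: [{time_min: 0.0, mg_per_kg: 10.0, duration_min: 60.0}]
t_end_min: 80640.0      # 56 days
n_points: 400
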