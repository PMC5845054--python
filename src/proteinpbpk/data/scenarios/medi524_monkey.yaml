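# MEDI-524, 30 mg/kg IV bolus, cynomolgus monkey
species: monkey
compound: medi_524
doses: [{time_min: 0.0, mg_per_kg: 30.0}]
t_end_min: 80640.0      # 56 days
n_points: 400
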