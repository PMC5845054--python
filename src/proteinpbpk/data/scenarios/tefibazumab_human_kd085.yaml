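# Tefibazumab, 10 mg/kg 15-min IV infusion, adapted FcRn Kd 0.85 uM
species: human
compound: tefibazumab_adapted
doses: [{time_min: 0.0, mg_per_kg: 10.0, duration_min: 15.0}]
t_end_min: 80640.0
n_points: 400
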