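# Inulin, 20 mg/kg IV bolus, rat (renal filtration f_GFR = 1, no endosomal uptake)
species: rat
compound: inulin
doses: [{time_min: 0.0, mg_per_kg: 20.0}]
t_end_min: 360.0
n_points: 400
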