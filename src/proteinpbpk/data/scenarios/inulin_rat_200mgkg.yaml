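# Inulin, 200 mg/kg IV bolus, rat (plasma-only readout at this dose)
species: rat
compound: inulin
doses: [{time_min: 0.0, mg_per_kg: 200.0}]
t_end_min: 360.0
n_points: 400
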