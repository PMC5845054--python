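# BAY 79-4620 ADC, 1.25 mg/kg IV bolus, tumor-bearing mouse (autoradiography dose)
species: mouse
compound: bay_79_4620
doses: [{time_min: 0.0, mg_per_kg: 1.25}]
t_end_min: 30240.0      # 21 days
n_points: 500
tumor: true
observations: [{tissue: tumor, residual_blood_fraction: 0.42}]
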