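# Rat reference physiology (~250 g), compiled from the Brown 1997
# compendium with rodent vascular/interstitial fractions as in mouse.yaml.
species: rat
body_weight_kg: 0.25
hematocrit: 0.46
gfr_ml_min: 1.31
blood_pools_l:
  arterial: 0.0030
  venous: 0.0052
  portal: 0.0008
portal_organs: [stomach, spleen, pancreas, small_intestine, large_intestine]
organs:
  fat:             {volume_l: 19.00e-3, f_vas: 0.010, f_int: 0.135, blood_flow_l_min: 6.64e-3}
  bone:            {volume_l: 18.25e-3, f_vas: 0.041, f_int: 0.100, blood_flow_l_min: 10.13e-3}
  brain:           {volume_l: 1.43e-3,  f_vas: 0.037, f_int: 0.180, blood_flow_l_min: 1.66e-3}
  gonads:          {volume_l: 0.63e-3,  f_vas: 0.014, f_int: 0.070, blood_flow_l_min: 0.25e-3}
  heart:           {volume_l: 0.83e-3,  f_vas: 0.260, f_int: 0.100, blood_flow_l_min: 4.07e-3}
  kidney:          {volume_l: 1.83e-3,  f_vas: 0.160, f_int: 0.200, blood_flow_l_min: 11.70e-3}
  large_intestine: {volume_l: 2.10e-3,  f_vas: 0.024, f_int: 0.094, blood_flow_l_min: 2.49e-3}
  small_intestine: {volume_l: 3.50e-3,  f_vas: 0.024, f_int: 0.094, blood_flow_l_min: 8.30e-3}
  liver:           {volume_l: 9.15e-3,  f_vas: 0.210, f_int: 0.163, blood_flow_l_min: 1.74e-3}
  lung:            {volume_l: 1.25e-3,  f_vas: 0.262, f_int: 0.188, blood_flow_l_min: null}
  muscle:          {volume_l: 101.0e-3, f_vas: 0.026, f_int: 0.118, blood_flow_l_min: 26.56e-3}
  pancreas:        {volume_l: 0.80e-3,  f_vas: 0.180, f_int: 0.120, blood_flow_l_min: 0.83e-3}
  skin:            {volume_l: 47.50e-3, f_vas: 0.019, f_int: 0.302, blood_flow_l_min: 6.64e-3}
  spleen:          {volume_l: 0.50e-3,  f_vas: 0.220, f_int: 0.150, blood_flow_l_min: 0.83e-3}
  stomach:         {volume_l: 1.15e-3,  f_vas: 0.032, f_int: 0.100, blood_flow_l_min: 1.16e-3}
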