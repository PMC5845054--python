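# Mouse reference physiology (~25 g), compiled from the Brown 1997
# compendium (organ weight and regional-flow fractions) with rodent
# vascular volume fractions from the Kawai 1994 compilation and rodent
# interstitial fractions from standard PBPK distribution tables.
# Units as in human.yaml.  Mouse is also the allometric reference
# species for the recirculation-flow scaling.
species: mouse
body_weight_kg: 0.025
hematocrit: 0.45
gfr_ml_min: 0.28
blood_pools_l:
  arterial: 0.00033
  venous: 0.00055
  portal: 0.00008
portal_organs: [stomach, spleen, pancreas, small_intestine, large_intestine]
organs:
  fat:             {volume_l: 1.75e-3,  f_vas: 0.010, f_int: 0.135, blood_flow_l_min: 1.365e-3}
  bone:            {volume_l: 2.68e-3,  f_vas: 0.041, f_int: 0.100, blood_flow_l_min: 1.960e-3}
  brain:           {volume_l: 0.413e-3, f_vas: 0.037, f_int: 0.180, blood_flow_l_min: 0.462e-3}
  gonads:          {volume_l: 0.012e-3, f_vas: 0.014, f_int: 0.070, blood_flow_l_min: 0.007e-3}
  heart:           {volume_l: 0.125e-3, f_vas: 0.260, f_int: 0.100, blood_flow_l_min: 0.924e-3}
  kidney:          {volume_l: 0.418e-3, f_vas: 0.160, f_int: 0.200, blood_flow_l_min: 1.274e-3}
  large_intestine: {volume_l: 0.270e-3, f_vas: 0.024, f_int: 0.094, blood_flow_l_min: 0.560e-3}
  small_intestine: {volume_l: 0.630e-3, f_vas: 0.024, f_int: 0.094, blood_flow_l_min: 1.540e-3}
  liver:           {volume_l: 1.370e-3, f_vas: 0.210, f_int: 0.163, blood_flow_l_min: 0.280e-3}
  lung:            {volume_l: 0.180e-3, f_vas: 0.262, f_int: 0.188, blood_flow_l_min: null}
  muscle:          {volume_l: 9.600e-3, f_vas: 0.026, f_int: 0.118, blood_flow_l_min: 3.626e-3}
  pancreas:        {volume_l: 0.100e-3, f_vas: 0.180, f_int: 0.120, blood_flow_l_min: 0.140e-3}
  skin:            {volume_l: 4.120e-3, f_vas: 0.019, f_int: 0.302, blood_flow_l_min: 1.512e-3}
  spleen:          {volume_l: 0.088e-3, f_vas: 0.220, f_int: 0.150, blood_flow_l_min: 0.140e-3}
  stomach:         {volume_l: 0.150e-3, f_vas: 0.032, f_int: 0.100, blood_flow_l_min: 0.210e-3}
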