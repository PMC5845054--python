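# Adult human reference physiology (male, ~73 kg), compiled from the
# ICRP-89 reference-person anatomy (organ volumes, regional blood flows,
# regional blood distribution) as used in standard whole-body PBPK
# physiology databases.  Vascular volume fractions (f_vas) are derived
# from the ICRP regional blood distribution (organ blood / organ volume);
# the remainder of the 5.3 l blood volume resides in the explicit
# arterial/venous/portal pools (heart chambers and great vessels).
# Units: volume_l in l; blood_flow_l_min in l/min (organ supply flow;
# liver: hepatic arterial only; lung flow is the total cardiac output and
# is derived at load time as the sum of all organ supply flows).
species: human
body_weight_kg: 73.0
hematocrit: 0.44
gfr_ml_min: 125.0
blood_pools_l:            # blood volumes of the pool compartments
  arterial: 0.86
  venous: 1.29
  portal: 0.18
portal_organs: [stomach, spleen, pancreas, small_intestine, large_intestine]
organs:
  fat:             {volume_l: 14.5,  f_vas: 0.0183, f_int: 0.135, blood_flow_l_min: 0.41925}
  bone:            {volume_l: 10.5,  f_vas: 0.0353, f_int: 0.100, blood_flow_l_min: 0.39}
  brain:           {volume_l: 1.45,  f_vas: 0.0440, f_int: 0.180, blood_flow_l_min: 0.78}
  gonads:          {volume_l: 0.035, f_vas: 0.0600, f_int: 0.070, blood_flow_l_min: 0.00325}
  heart:           {volume_l: 0.33,  f_vas: 0.1600, f_int: 0.100, blood_flow_l_min: 0.26}
  kidney:          {volume_l: 0.31,  f_vas: 0.3400, f_int: 0.200, blood_flow_l_min: 1.235}
  large_intestine: {volume_l: 0.37,  f_vas: 0.3150, f_int: 0.094, blood_flow_l_min: 0.26}
  small_intestine: {volume_l: 0.64,  f_vas: 0.3150, f_int: 0.094, blood_flow_l_min: 0.65}
  liver:           {volume_l: 1.80,  f_vas: 0.2900, f_int: 0.163, blood_flow_l_min: 0.325}
  lung:            {volume_l: 0.53,  f_vas: 0.4000, f_int: 0.188, blood_flow_l_min: null}
  muscle:          {volume_l: 29.0,  f_vas: 0.0256, f_int: 0.118, blood_flow_l_min: 1.4625}
  pancreas:        {volume_l: 0.14,  f_vas: 0.2300, f_int: 0.120, blood_flow_l_min: 0.065}
  skin:            {volume_l: 3.30,  f_vas: 0.0480, f_int: 0.302, blood_flow_l_min: 0.39}
  spleen:          {volume_l: 0.15,  f_vas: 0.4900, f_int: 0.150, blood_flow_l_min: 0.195}
  stomach:         {volume_l: 0.15,  f_vas: 0.3500, f_int: 0.100, blood_flow_l_min: 0.065}
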