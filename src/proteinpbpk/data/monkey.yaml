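# Cynomolgus monkey reference physiology (~3.5 kg), compiled from
# standard non-human-primate compendia; vascular volume fractions use the
# primate (human-derived) set, flows are fractions of an allometric
# cardiac output of ~0.60 l/min.
species: monkey
body_weight_kg: 3.5
hematocrit: 0.41
gfr_ml_min: 7.0
blood_pools_l:
  arterial: 0.022
  venous: 0.037
  portal: 0.006
portal_organs: [stomach, spleen, pancreas, small_intestine, large_intestine]
organs:
  fat:             {volume_l: 0.300,  f_vas: 0.0183, f_int: 0.135, blood_flow_l_min: 0.0330}
  bone:            {volume_l: 0.330,  f_vas: 0.0353, f_int: 0.100, blood_flow_l_min: 0.0360}
  brain:           {volume_l: 0.075,  f_vas: 0.0440, f_int: 0.180, blood_flow_l_min: 0.0480}
  gonads:          {volume_l: 0.002,  f_vas: 0.0600, f_int: 0.070, blood_flow_l_min: 0.0003}
  heart:           {volume_l: 0.012,  f_vas: 0.1600, f_int: 0.100, blood_flow_l_min: 0.0270}
  kidney:          {volume_l: 0.016,  f_vas: 0.3400, f_int: 0.200, blood_flow_l_min: 0.0900}
  large_intestine: {volume_l: 0.040,  f_vas: 0.3150, f_int: 0.094, blood_flow_l_min: 0.0270}
  small_intestine: {volume_l: 0.070,  f_vas: 0.3150, f_int: 0.094, blood_flow_l_min: 0.0720}
  liver:           {volume_l: 0.095,  f_vas: 0.2900, f_int: 0.163, blood_flow_l_min: 0.0300}
  lung:            {volume_l: 0.018,  f_vas: 0.4000, f_int: 0.188, blood_flow_l_min: null}
  muscle:          {volume_l: 1.550,  f_vas: 0.0256, f_int: 0.118, blood_flow_l_min: 0.1557}
  pancreas:        {volume_l: 0.005,  f_vas: 0.2300, f_int: 0.120, blood_flow_l_min: 0.0072}
  skin:            {volume_l: 0.370,  f_vas: 0.0480, f_int: 0.302, blood_flow_l_min: 0.0480}
  spleen:          {volume_l: 0.003,  f_vas: 0.4900, f_int: 0.150, blood_flow_l_min: 0.0168}
  stomach:         {volume_l: 0.015,  f_vas: 0.3500, f_int: 0.100, blood_flow_l_min: 0.0090}
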