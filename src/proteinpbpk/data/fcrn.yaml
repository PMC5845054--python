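# FcRn binding model parameters.
# Global rate constants (all species):
#   k_up   endosomal uptake rate constant, 1/min
#   k_rec  endosomal recycling rate constant, 1/min
#   k_ass  association rate constant for FcRn binding, l/umol/min
# Species dependent:
#   igg_plasma_umol_l  plasma concentration of endogenous IgG, umol/l
#   kd_igg_acidic      Kd of endogenous IgG to FcRn in endosomal space, umol/l
#   free_fcrn_umol_l   free endosomal FcRn concentration, umol/l
# Rat FcRn/IgG parameters are not separately tabulated; the mouse values
# are used (rat is only exercised with inulin, which neither binds FcRn
# nor undergoes endosomal uptake).
k_up: 0.294
k_rec: 0.0888
k_ass: 0.87
f_vas_up: 1.0
f_vas_rec: 1.0
kd_igg_neutral: 99999.0
species:
  mouse:  {igg_plasma_umol_l: 18.0, kd_igg_acidic: 0.75,  free_fcrn_umol_l: 38.7}
  rat:    {igg_plasma_umol_l: 18.0, kd_igg_acidic: 0.75,  free_fcrn_umol_l: 38.7}
  monkey: {igg_plasma_umol_l: 75.0, kd_igg_acidic: 0.132, free_fcrn_umol_l: 21.0}
  human:  {igg_plasma_umol_l: 70.0, kd_igg_acidic: 0.63,  free_fcrn_umol_l: 80.8}
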