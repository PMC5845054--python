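# Bundled compound library.
# molecular_weight_g_mol is used only for mg/kg dose conversion.
# radius_nm: hydrodynamic radius.
# kd_fcrn_acidic_umol_l: FcRn dissociation constant in the acidic
#   endosomal space; 999999 marks virtually no binding (no Fc region).
# kd_fcrn_neutral_umol_l defaults to 999999 (no binding at neutral pH).
# f_gfr: glomerular filtration coefficient (renal clearance f_gfr*GFR).
# no_endosomal_uptake: disables endosomal uptake (k_up = 0).
antibody_7e3:
  molecular_weight_g_mol: 150000.0
  radius_nm: 5.34
  kd_fcrn_acidic_umol_l: 0.75
bay_79_4620:
  molecular_weight_g_mol: 152000.0
  radius_nm: 5.34
  kd_fcrn_acidic_umol_l: 12.7
  target:
    name: ca_ix
    kd_umol_l: 0.004
    k_on_l_umol_min: 6.0        # not printed; typical antibody on-rate 1e5 /M/s
    turnover_half_life_h: 38.0
    baseline_umol_l: 0.26
    k_int_per_min: 0.027
medi_524:
  molecular_weight_g_mol: 150000.0
  radius_nm: 5.34
  kd_fcrn_acidic_umol_l: 1.196
medi_524_yte:
  molecular_weight_g_mol: 150000.0
  radius_nm: 5.34
  kd_fcrn_acidic_umol_l: 0.134
cda1:
  molecular_weight_g_mol: 150000.0
  radius_nm: 5.34
  kd_fcrn_acidic_umol_l: 0.63
tefibazumab:
  molecular_weight_g_mol: 150000.0
  radius_nm: 5.34
  kd_fcrn_acidic_umol_l: 0.63
tefibazumab_adapted:
  molecular_weight_g_mol: 150000.0
  radius_nm: 5.34
  kd_fcrn_acidic_umol_l: 0.85
domain_antibody:
  molecular_weight_g_mol: 25600.0
  radius_nm: 2.43
  kd_fcrn_acidic_umol_l: 999999.0
  f_gfr: 0.24
inulin:
  molecular_weight_g_mol: 5500.0
  radius_nm: 1.39
  kd_fcrn_acidic_umol_l: 999999.0
  no_endosomal_uptake: true
  f_gfr: 1.0
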