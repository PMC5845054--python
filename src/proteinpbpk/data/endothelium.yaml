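# Vascular endothelium properties per organ (species independent).
# Lp: hydraulic conductivity, ml/min/N
# alpha_L: fraction of transcapillary fluid conductance via large pores
# r_S, r_L: small/large pore radii, nm
# Two endothelium classes: continuous (alpha_L 0.05, 4.5/25 nm) for most
# organs, discontinuous (alpha_L 0.80, 9/33 nm) for liver and spleen.
bone:            {Lp: 3.24e-4, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
brain:           {Lp: 1.80e-6, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
fat:             {Lp: 3.24e-4, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
gonads:          {Lp: 3.24e-4, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
heart:           {Lp: 5.16e-4, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
kidney:          {Lp: 4.50e-3, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
large_intestine: {Lp: 6.73e-3, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
liver:           {Lp: 1.40e-3, alpha_L: 0.80, r_S: 9.0, r_L: 33.0}
lung:            {Lp: 2.04e-4, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
muscle:          {Lp: 3.24e-4, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
pancreas:        {Lp: 1.16e-3, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
skin:            {Lp: 7.01e-4, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
small_intestine: {Lp: 5.54e-3, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
spleen:          {Lp: 1.40e-3, alpha_L: 0.80, r_S: 9.0, r_L: 33.0}
stomach:         {Lp: 1.43e-3, alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
# The lumped endogenous-IgG pool uses the continuous-endothelium pore
# geometry; its Lp is the vascular-surface-area-weighted mean over all
# tissues and is computed from the species physiology at load time.
igg_pool:        {Lp: null,    alpha_L: 0.05, r_S: 4.5, r_L: 25.0}
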