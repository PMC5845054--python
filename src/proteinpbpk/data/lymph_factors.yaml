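# Lymph and recirculation flow factors (species independent).
# f_lymph: organ lymph flow as fraction of the organ plasma supply flow
#          (liver: hepatic arterial supply; lung: total cardiac output).
# f_Jiso: recirculation flow as fraction of the small-pore lymph flow,
#         before the organ-volume allometric factor.
bone:            {f_lymph: 6.62e-4, f_Jiso: 0.960}
brain:           {f_lymph: 7.27e-5, f_Jiso: 0.404}
fat:             {f_lymph: 7.54e-3, f_Jiso: 0.357}
gonads:          {f_lymph: 1.11e-2, f_Jiso: 0.960}
heart:           {f_lymph: 1.47e-3, f_Jiso: 0.960}
kidney:          {f_lymph: 7.09e-4, f_Jiso: 0.761}
large_intestine: {f_lymph: 1.44e-2, f_Jiso: 0.179}
liver:           {f_lymph: 1.99e-2, f_Jiso: 0.960}
lung:            {f_lymph: 3.56e-5, f_Jiso: 0.010}
muscle:          {f_lymph: 2.01e-3, f_Jiso: 0.292}
pancreas:        {f_lymph: 3.03e-2, f_Jiso: 0.010}
skin:            {f_lymph: 3.52e-3, f_Jiso: 0.617}
small_intestine: {f_lymph: 1.95e-3, f_Jiso: 0.179}
spleen:          {f_lymph: 1.99e-2, f_Jiso: 0.010}
stomach:         {f_lymph: 2.04e-3, f_Jiso: 0.960}
tumor:           {f_lymph: 3.65e-3, f_Jiso: 0.281}
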