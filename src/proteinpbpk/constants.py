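"""Physical constants and model-wide defaults.

Canonical internal units: volumes in l, time in min, amounts in µmol,
concentrations in µmol/l.  Pore-level quantities use cm (lengths),
N (forces) and min, matching the units in which the vascular-wall
parameters are tabulated.
"""

# Gas constant x body temperature (37 degC), N*cm/mol
RT = 2.58e5

# Avogadro constant, 1/mol
N_AVOGADRO = 6.022e23

# Viscosity of water at body temperature, N*min/cm^2
ETA_WATER = 1.17e-9

# Proportionality constant relating capillary surface area to vascular
# volume, cm^2 per litre of vascular space (calibrated against the
# ~300 m^2 total human capillary endothelial surface).
K_SURFACE = 950_000.0

# Fraction of endosomal space within the vascular endothelium
F_ENDO = 0.2

# Endothelium thickness, cm (0.3 um)
D_ENDOTHELIUM = 0.3e-4

# Allometric exponent for the fluid recirculation flow
GAMMA_JISO = 2.0 / 3.0

# Interstitial/plasma partition coefficient (fraction unbound 1)
K_IV = 0.96

# Dissociation constants representing "virtually no binding" at neutral pH
KD_NEUTRAL_DRUG = 999_999.0   # umol/l
KD_NEUTRAL_IGG = 99_999.0     # umol/l

NM_TO_CM = 1e-7
ML_TO_L = 1e-3
CM3_TO_L = 1e-3
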