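"""Endogenous IgG / FcRn pool: analytic drug-free steady state.

For each species, prints the lumped-pool steady state used as the
simulation initial condition: interstitial and endosomal IgG, the
IgG-FcRn complex, the implied total FcRn, and the zero-order IgG
synthesis rate that balances catabolism.
"""

from proteinpbpk import build_igg_pool, igg_steady_state, load_species
from proteinpbpk.config import load_fcrn_defaults

rates, pools, k_ass = load_fcrn_defaults()
for name in ("mouse", "monkey", "human"):
    sp = load_species(name)
    ss = igg_steady_state(build_igg_pool(sp), pools[name], rates, k_ass)
    print(f"\n=== {name} ===")
    print(f"plasma IgG            : {ss.C_plasma:7.1f} umol/l (homeostatic)")
    print(f"interstitial IgG      : {ss.C_interstitial:7.1f} umol/l")
    print(f"endosomal free IgG    : {ss.C_endo_free:7.2f} umol/l")
    print(f"IgG-FcRn complex      : {ss.C_complex:7.1f} umol/l")
    print(f"free / total FcRn     : {ss.C_fcrn_free:.1f} / {ss.C_fcrn_total:.1f} umol/l")
    print(f"IgG synthesis         : {ss.synthesis_rate * 1440:.3g} umol/day")
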