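"""Dose linearity of antibody exposure in the human.

Simulates the three bundled CDA1 infusion doses (5, 10, 20 mg/kg) and
prints dose-normalized AUC and clearance.  At antibody doses the
endogenous-IgG pool buffers FcRn occupancy, so exposure is close to
dose proportional.
"""

from proteinpbpk import auc, build_from_config, load_scenario, simulate

for mg_kg in (5, 10, 20):
    cfg = load_scenario(f"cda1_human_{mg_kg}mgkg")
    model, doses, kwargs = build_from_config(cfg)
    res = simulate(model, doses, **kwargs)
    a = auc(res.t, res.plasma_concentration())
    dose = sum(d.amount for d in doses)
    print(f"CDA1 {mg_kg:2d} mg/kg: AUC = {a:9.0f} umol*min/l, "
          f"AUC/dose = {a / dose:7.1f} min/l, CL = {dose / a * 1e6:.1f} ul/min")
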