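"""Deterministic reduced-model fixtures for oracle and regression tests.

Each fixture is small enough that an independent reference (closed form
or a hand-coded ODE solved by a different integrator) is cheap to
compute at test time.  Fixtures are reproducible bit-for-bit from their
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FixtureModel", "make_fixture"]


@dataclass(frozen=True)
class FixtureModel:
    """A reduced synthetic model with its reference solution inputs."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)


def make_fixture(kind: str, seed: int = 0) -> FixtureModel:
    """Create a deterministic fixture.

    Kinds
    -----
    one_compartment_analytic
        Single well-stirred volume V with linear clearance CL; reference
        is the closed form C0·exp(−CL/V·t).
    two_organ_oracle
        Two organs (one continuous-, one discontinuous-endothelium-like)
        in a closed plasma loop with two-pore exchange and lymph return;
        parameters drawn reproducibly from the seed within physiologic
        ranges.  The reference trajectory is an independently hand-coded
        ODE in the test suite.
    igg_steady_state
        Small lumped pool for the drug-free IgG/FcRn stationarity oracle.
    """
    rng = np.random.default_rng(seed)
    if kind == "one_compartment_analytic":
        return FixtureModel(kind, seed, {
            "V_l": 0.003, "CL_l_min": 2.0e-5, "dose_umol": 1.0e-3,
        })
    if kind == "two_organ_oracle":
        params = {
            "V_pls": 0.001,
            "organs": [
                {
                    "name": "cont",
                    "V_int": float(rng.uniform(0.5e-3, 2e-3)),
                    "Q_pls": float(rng.uniform(1e-3, 5e-3)),
                    "Lp": 3.24e-4, "alpha_L": 0.05, "r_S": 4.5, "r_L": 25.0,
                    "S_cm2": float(rng.uniform(50, 500)),
                    "f_lymph": float(rng.uniform(1e-3, 1e-2)),
                    "f_Jiso": float(rng.uniform(0.0, 0.96)),
                },
                {
                    "name": "disc",
                    "V_int": float(rng.uniform(0.1e-3, 0.5e-3)),
                    "Q_pls": float(rng.uniform(0.5e-3, 2e-3)),
                    "Lp": 1.40e-3, "alpha_L": 0.80, "r_S": 9.0, "r_L": 33.0,
                    "S_cm2": float(rng.uniform(20, 200)),
                    "f_lymph": float(rng.uniform(5e-3, 2e-2)),
                    "f_Jiso": float(rng.uniform(0.0, 0.96)),
                },
            ],
            "a_e_nm": float(rng.uniform(1.0, 6.0)),
            "dose_umol": 1.0e-3,
        }
        return FixtureModel(kind, seed, params)
    if kind == "igg_steady_state":
        return FixtureModel(kind, seed, {"species": "mouse"})
    raise ValueError(f"unknown fixture kind {kind!r}")
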