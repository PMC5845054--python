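"""Shared fixtures: bundled species/compounds and synthetic reduced models."""

from __future__ import annotations

import numpy as np
import pytest

from proteinpbpk.constants import K_SURFACE
from proteinpbpk.physiology import OrganPhysiology, SpeciesPhysiology, load_species


@pytest.fixture(scope="session")
def human():
    return load_species("human")


@pytest.fixture(scope="session")
def mouse():
    return load_species("mouse")


def make_reduced_species(params: dict) -> SpeciesPhysiology:
    """Three-compartment reduced species: a pass-through lung connector and
    two exchanging organs (named liver/kidney to satisfy the topology),
    built from a two-organ oracle fixture's parameters."""
    hct = 0.45
    organs = {}
    specs = {
        "liver": params["organs"][1],   # discontinuous-like
        "kidney": params["organs"][0],  # continuous-like
    }
    co_blood = sum(o["Q_pls"] for o in specs.values()) / (1 - hct)
    for name, o in specs.items():
        organs[name] = OrganPhysiology(
            name=name,
            V_org=o["V_int"] / 0.3,   # 30% interstitial
            f_vas=o["S_cm2"] / K_SURFACE / (o["V_int"] / 0.3),
            f_int=0.3,
            f_cell=0.2,
            Q_blood=o["Q_pls"] / (1 - hct),
            Lp=o["Lp"],
            alpha_L=o["alpha_L"],
            r_S=o["r_S"],
            r_L=o["r_L"],
            f_lymph=o["f_lymph"],
            f_Jiso=o["f_Jiso"],
        )
    organs["lung"] = OrganPhysiology(
        name="lung", V_org=2e-4, f_vas=0.2, f_int=0.2, f_cell=0.5,
        Q_blood=co_blood, Lp=2.04e-4, alpha_L=0.05, r_S=4.5, r_L=25.0,
        f_lymph=3.56e-5, f_Jiso=0.01,
    )
    return SpeciesPhysiology(
        name="mouse",  # reuse bundled mouse FcRn parameters
        body_weight=0.025,
        HCT=hct,
        GFR=0.28e-3,
        organs=organs,
        portal_organs=(),
        blood_pools={"arterial": 3e-4, "venous": 5e-4, "portal": 1e-4},
        mouse_reference_volumes={},   # own volumes -> allometric factor 1
    )


@pytest.fixture
def inert_compound():
    """A compound nothing can touch: too large for every pore, no FcRn
    binding, no endosomal uptake, no renal filtration."""
    from proteinpbpk.assembly import CompoundProperties
    from proteinpbpk.fcrn import FcRnBindingParams
    from proteinpbpk.twopore import SoluteGeometry

    return CompoundProperties(
        name="inert_giant",
        molecular_weight=150000.0,
        geometry=SoluteGeometry(a_e=50.0),
        fcrn=FcRnBindingParams(k_ass=0.87, Kd_acidic=999999.0),
        no_endosomal_uptake=True,
    )
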