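"""Species and organ physiology: parameter database plus derived quantities.

Loads the bundled per-species YAML tables (organ volumes, sub-compartment
fractions, blood flows, hematocrit, GFR), merges in the species-independent
endothelium and lymph/recirculation factor tables, and exposes all
physiology-derived quantities: capillary surface areas, endosomal volumes,
lymph and recirculation flows, and the lumped endogenous-IgG pool.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import yaml

from .constants import D_ENDOTHELIUM, F_ENDO, GAMMA_JISO, K_SURFACE

__all__ = [
    "OrganPhysiology",
    "SpeciesPhysiology",
    "IgGPoolPhysiology",
    "load_species",
    "available_species",
    "capillary_surface_area",
    "endosomal_volume",
    "lymph_flow",
    "recirculation_flow",
    "build_igg_pool",
]

AVAILABLE_SPECIES = ("mouse", "rat", "monkey", "human")


def _read_yaml(name: str) -> dict:
    ref = resources.files("proteinpbpk.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class OrganPhysiology:
    """One organ's anatomy, perfusion and endothelial wall properties.

    Units: volumes l, flows l/min, Lp ml/min/N, pore radii nm.
    ``Q_blood`` is the organ's supply blood flow — hepatic arterial flow
    for liver, total cardiac output for lung (lung sits in series).
    """

    name: str
    V_org: float
    f_vas: float
    f_int: float
    f_cell: float
    Q_blood: float
    Lp: float
    alpha_L: float
    r_S: float
    r_L: float
    f_lymph: float
    f_Jiso: float

    def __post_init__(self) -> None:
        if self.V_org <= 0:
            raise ValueError(f"{self.name}: organ volume must be positive")
        if min(self.f_vas, self.f_int, self.f_cell) < 0:
            raise ValueError(f"{self.name}: negative volume fraction")
        if self.f_vas + self.f_int + self.f_cell > 1.0 + 1e-9:
            raise ValueError(f"{self.name}: volume fractions exceed 1")
        if not 0 <= self.alpha_L <= 1:
            raise ValueError(f"{self.name}: alpha_L outside [0, 1]")
        if self.r_S >= self.r_L:
            raise ValueError(f"{self.name}: small-pore radius must be < large-pore radius")
        if self.f_lymph < 0 or not 0 <= self.f_Jiso <= 1:
            raise ValueError(f"{self.name}: invalid lymph/recirculation factor")
        if self.Q_blood < 0 or self.Lp < 0:
            raise ValueError(f"{self.name}: negative flow or conductivity")


def capillary_surface_area(organ: OrganPhysiology, k: float = K_SURFACE) -> float:
    """Capillary endothelial surface area in cm²: S = k · f_vas · V.

    The heuristic assumes similar vascular-tree morphology across organs,
    so surface per organ volume tracks capillary density, which in turn
    tracks the vascular volume fraction.
    """
    if k <= 0:
        raise ValueError("proportionality constant must be positive")
    return k * organ.f_vas * organ.V_org


def endosomal_volume(
    organ: OrganPhysiology,
    k: float = K_SURFACE,
    f_endo: float = F_ENDO,
    d_e_cm: float = D_ENDOTHELIUM,
) -> float:
    """Endosomal space volume in l: V_endo = f_endo · d_e · S."""
    if f_endo < 0 or d_e_cm < 0:
        raise ValueError("endosome fraction and thickness must be nonnegative")
    s_cm2 = capillary_surface_area(organ, k)
    return f_endo * d_e_cm * s_cm2 * 1e-3  # cm^3 -> l


def lymph_flow(organ: OrganPhysiology, hct: float) -> float:
    """Organ lymph flow in l/min: L = f_lymph · Q_blood · (1 − HCT)."""
    if not 0 < hct < 1:
        raise ValueError("hematocrit must be in (0, 1)")
    return organ.f_lymph * organ.Q_blood * (1.0 - hct)


def recirculation_flow(
    organ: OrganPhysiology,
    hct: float,
    mouse_reference_volume: float | None,
    gamma: float = GAMMA_JISO,
) -> float:
    """Isogravimetric recirculation flow in l/min with allometric scaling.

    J_iso = f_Jiso · (1 − alpha_L) · L · (V_species/V_mouse)^(gamma − 1);
    in the mouse reference the volume ratio is 1 by construction.
    """
    L = lymph_flow(organ, hct)
    base = organ.f_Jiso * (1.0 - organ.alpha_L) * L
    if mouse_reference_volume is None:
        raise ValueError(f"{organ.name}: mouse reference volume required for allometric scaling")
    return base * (organ.V_org / mouse_reference_volume) ** (gamma - 1.0)


@dataclass(frozen=True)
class IgGPoolPhysiology:
    """Lumped whole-body compartment for the endogenous IgG/FcRn sub-model.

    Extensive quantities (volumes, flows, surface area) are sums over all
    organs; Lp is the vascular-surface-area-weighted mean; the pore
    geometry is the continuous-endothelium standard.
    """

    V_plasma: float
    V_int: float
    V_endo: float
    S: float
    L: float
    J_iso: float
    Lp: float
    alpha_L: float = 0.05
    r_S: float = 4.5
    r_L: float = 25.0


@dataclass(frozen=True)
class SpeciesPhysiology:
    """A species' full organ set, blood pools and whole-body constants."""

    name: str
    body_weight: float          # kg
    HCT: float
    GFR: float                  # l/min
    organs: dict[str, OrganPhysiology]
    portal_organs: tuple[str, ...]
    blood_pools: dict[str, float]   # blood volumes, l
    mouse_reference_volumes: dict[str, float]
    k: float = K_SURFACE
    f_endo: float = F_ENDO
    d_e: float = D_ENDOTHELIUM      # cm
    gamma_Jiso: float = GAMMA_JISO

    def __post_init__(self) -> None:
        if not 0 < self.HCT < 1:
            raise ValueError("hematocrit must be in (0, 1)")
        for name in self.portal_organs:
            if name not in self.organs:
                raise ValueError(f"unknown portal organ {name!r}")

    # -- derived whole-body quantities -------------------------------------

    @property
    def cardiac_output(self) -> float:
        """Total blood cardiac output, l/min (= lung supply flow)."""
        return self.organs["lung"].Q_blood

    @property
    def cardiac_output_plasma(self) -> float:
        return self.cardiac_output * (1.0 - self.HCT)

    def capillary_surface_area(self, organ: OrganPhysiology) -> float:
        return capillary_surface_area(organ, self.k)

    def endosomal_volume(self, organ: OrganPhysiology) -> float:
        return endosomal_volume(organ, self.k, self.f_endo, self.d_e)

    def lymph_flow(self, organ: OrganPhysiology) -> float:
        return lymph_flow(organ, self.HCT)

    def recirculation_flow(self, organ: OrganPhysiology) -> float:
        ref = self.mouse_reference_volumes.get(organ.name, organ.V_org)
        return recirculation_flow(organ, self.HCT, ref, self.gamma_Jiso)

    def total_capillary_surface_area(self) -> float:
        """Whole-body capillary endothelial surface, cm²."""
        return sum(self.capillary_surface_area(o) for o in self.organs.values())

    def total_lymph_flow(self) -> float:
        """Sum of all organ lymph flows, l/min."""
        return sum(self.lymph_flow(o) for o in self.organs.values())

    def total_lymph_fraction_of_plasma_flow(self) -> float:
        """Total lymph flow as a fraction of cardiac-output plasma flow."""
        return self.total_lymph_flow() / self.cardiac_output_plasma

    def organ_plasma_volume(self, organ: OrganPhysiology) -> float:
        return organ.f_vas * organ.V_org * (1.0 - self.HCT)

    def pool_plasma_volume(self) -> float:
        """Systemic plasma volume: organ vascular plasma plus blood pools."""
        organ_pls = sum(self.organ_plasma_volume(o) for o in self.organs.values())
        pool_pls = sum(self.blood_pools.values()) * (1.0 - self.HCT)
        return organ_pls + pool_pls


def build_igg_pool(species: SpeciesPhysiology) -> IgGPoolPhysiology:
    """Lump all organs into the endogenous-IgG pool compartment.

    Extensive parameters are organ sums; Lp is the surface-area-weighted
    mean.  The pooled plasma volume additionally includes the arterial,
    venous and portal blood-pool plasma, since endogenous IgG pervades
    the whole systemic plasma.
    """
    organs = list(species.organs.values())
    if not organs:
        raise ValueError("species has no organs")
    S_each = [species.capillary_surface_area(o) for o in organs]
    S_tot = sum(S_each)
    return IgGPoolPhysiology(
        V_plasma=species.pool_plasma_volume(),
        V_int=sum(o.f_int * o.V_org for o in organs),
        V_endo=sum(species.endosomal_volume(o) for o in organs),
        S=S_tot,
        L=species.total_lymph_flow(),
        J_iso=sum(species.recirculation_flow(o) for o in organs),
        Lp=sum(o.Lp * s for o, s in zip(organs, S_each)) / S_tot,
    )


def available_species() -> tuple[str, ...]:
    return AVAILABLE_SPECIES


def load_species(name: str) -> SpeciesPhysiology:
    """Load a bundled species physiology by name.

    Merges the species file with the shared endothelium and
    lymph/recirculation factor tables, fills the lung supply flow with
    the total cardiac output (sum of all organ supply flows) and attaches
    the mouse reference organ volumes used by the allometric
    recirculation-flow scaling.
    """
    if name not in AVAILABLE_SPECIES:
        raise KeyError(f"unknown species {name!r}; available: {AVAILABLE_SPECIES}")
    raw = _read_yaml(f"{name}.yaml")
    endo = _read_yaml("endothelium.yaml")
    lymph = _read_yaml("lymph_factors.yaml")
    mouse_raw = raw if name == "mouse" else _read_yaml("mouse.yaml")
    mouse_ref = {k: v["volume_l"] for k, v in mouse_raw["organs"].items()}

    flows = [v["blood_flow_l_min"] for v in raw["organs"].values() if v["blood_flow_l_min"] is not None]
    cardiac_output = sum(flows)

    organs: dict[str, OrganPhysiology] = {}
    for oname, rec in raw["organs"].items():
        if oname not in endo or oname not in lymph:
            raise KeyError(f"organ {oname!r} missing from endothelium/lymph tables")
        q = rec["blood_flow_l_min"]
        organs[oname] = OrganPhysiology(
            name=oname,
            V_org=rec["volume_l"],
            f_vas=rec["f_vas"],
            f_int=rec["f_int"],
            f_cell=max(0.0, 1.0 - rec["f_vas"] - rec["f_int"]),
            Q_blood=cardiac_output if q is None else q,
            Lp=endo[oname]["Lp"],
            alpha_L=endo[oname]["alpha_L"],
            r_S=endo[oname]["r_S"],
            r_L=endo[oname]["r_L"],
            f_lymph=lymph[oname]["f_lymph"],
            f_Jiso=lymph[oname]["f_Jiso"],
        )
    return SpeciesPhysiology(
        name=raw["species"],
        body_weight=raw["body_weight_kg"],
        HCT=raw["hematocrit"],
        GFR=raw["gfr_ml_min"] * 1e-3,
        organs=organs,
        portal_organs=tuple(raw["portal_organs"]),
        blood_pools=dict(raw["blood_pools_l"]),
        mouse_reference_volumes=mouse_ref,
    )
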