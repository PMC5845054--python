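"""Whole-body ODE assembly: state layout, flow topology and all fluxes.

The circulation follows the standard whole-body layout: an arterial
plasma pool feeds every organ in parallel; the splanchnic organs
(stomach, spleen, pancreas, small and large intestine) drain into the
portal vein pool which perfuses the liver together with the hepatic
artery; all other organs (and the liver) drain into the venous pool;
the lung sits in series on the total cardiac output between the venous
and arterial pools.  Each organ exchanges drug between its plasma and
interstitial sub-compartments through the two-pore law, returns
interstitial drug to the venous pool via lymph, and cycles drug through
its endosomal space (uptake, FcRn binding against the pooled free-FcRn
concentration, recycling, catabolism).  Optional processes: glomerular
filtration from the kidney plasma, and a tumor organ carrying an
interstitial target with turnover, reversible drug binding and
first-order internalization of the complex.

States are amounts in µmol.  Cellular sub-compartments are represented
in the state layout but carry no drug (passive cellular permeability is
neglected for macromolecules); they are kept for structural fidelity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import K_IV, KD_NEUTRAL_DRUG
from .fcrn import (
    EndogenousIgGPool,
    EndosomalRates,
    FcRnBindingParams,
    IgGSteadyState,
    igg_steady_state,
    pool_coefficients,
)
from .physiology import IgGPoolPhysiology, OrganPhysiology, SpeciesPhysiology
from .twopore import SoluteGeometry, TwoPoreCoefficients, organ_coefficients

__all__ = [
    "CompoundProperties",
    "TargetBindingParams",
    "TumorOrganParams",
    "DoseEvent",
    "ModelDefinition",
    "build_model",
    "add_tumor_organ",
    "lymph_return_flux",
    "renal_clearance_flux",
    "load_tumor_params",
]


# --------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class TargetBindingParams:
    """Interstitial target with turnover and complex internalization.

    The target is synthesized at zero order and degraded at first order
    (k_deg = ln 2 / turnover half-life), which holds its drug-free
    concentration at the baseline.  Drug binds reversibly (Kd, k_on) and
    the drug-target complex is internalized at ``k_int``, eliminating
    the drug.
    """

    Kd: float                  # µmol/l
    k_on: float                # l/µmol/min
    turnover_half_life_h: float
    baseline: float            # µmol/l at t = 0
    k_int: float               # 1/min

    def __post_init__(self) -> None:
        if min(self.Kd, self.k_on, self.turnover_half_life_h, self.baseline, self.k_int) <= 0:
            raise ValueError("target binding parameters must be positive")

    @property
    def k_deg(self) -> float:
        return math.log(2.0) / (self.turnover_half_life_h * 60.0)

    @property
    def synthesis(self) -> float:
        """Zero-order synthesis in concentration units, µmol/l/min."""
        return self.k_deg * self.baseline


@dataclass(frozen=True)
class CompoundProperties:
    """Everything the model needs to know about one compound."""

    name: str
    molecular_weight: float            # g/mol, used only for mg/kg dosing
    geometry: SoluteGeometry
    fcrn: FcRnBindingParams
    no_endosomal_uptake: bool = False
    f_GFR: float | None = None
    target: TargetBindingParams | None = None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")
        if self.f_GFR is not None and not 0 <= self.f_GFR <= 1:
            raise ValueError("f_GFR must be in [0, 1]")

    def dose_umol(self, mg_per_kg: float, body_weight_kg: float) -> float:
        """Convert an mg/kg dose to µmol via the molecular weight."""
        return mg_per_kg * body_weight_kg * 1000.0 / self.molecular_weight


@dataclass(frozen=True)
class TumorOrganParams:
    """Tumor organ with the same structure as a standard organ."""

    volume_ml: float
    specific_blood_flow_ml_min_g: float
    f_vas: float
    f_int: float
    Lp: float
    alpha_L: float
    r_S: float
    r_L: float
    f_lymph: float
    f_Jiso: float

    def as_organ(self) -> OrganPhysiology:
        v_l = self.volume_ml * 1e-3
        q = self.specific_blood_flow_ml_min_g * self.volume_ml * 1e-3  # density ~1 g/ml
        return OrganPhysiology(
            name="tumor",
            V_org=v_l,
            f_vas=self.f_vas,
            f_int=self.f_int,
            f_cell=max(0.0, 1.0 - self.f_vas - self.f_int),
            Q_blood=q,
            Lp=self.Lp,
            alpha_L=self.alpha_L,
            r_S=self.r_S,
            r_L=self.r_L,
            f_lymph=self.f_lymph,
            f_Jiso=self.f_Jiso,
        )


def load_tumor_params() -> TumorOrganParams:
    """The bundled a priori tumor parameter set (xenograft)."""
    import importlib.resources as resources

    import yaml

    with resources.files("proteinpbpk.data").joinpath("tumor.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return TumorOrganParams(
        volume_ml=raw["volume_ml"],
        specific_blood_flow_ml_min_g=raw["specific_blood_flow_ml_min_g"],
        f_vas=raw["f_vas"],
        f_int=raw["f_int"],
        Lp=raw["Lp"],
        alpha_L=raw["alpha_L"],
        r_S=raw["r_S"],
        r_L=raw["r_L"],
        f_lymph=raw["f_lymph"],
        f_Jiso=raw["f_Jiso"],
    )


@dataclass(frozen=True)
class DoseEvent:
    """IV dose: bolus into venous plasma, or constant-rate infusion."""

    time: float                 # min
    amount: float               # µmol
    duration: float = 0.0       # min; 0 means bolus

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.duration < 0:
            raise ValueError("infusion duration must be nonnegative")


# --------------------------------------------------------------------------
# Elementary fluxes (exposed for direct use and testing)


def lymph_return_flux(C_i_org: float, L_org: float) -> float:
    """Lymph return of interstitial drug to the venous plasma pool, µmol/min."""
    if L_org < 0:
        raise ValueError("lymph flow must be nonnegative")
    return L_org * C_i_org


def renal_clearance_flux(C_plasma_kidney: float, f_GFR: float, GFR: float) -> float:
    """Glomerular filtration from kidney plasma: CL_ren·C = f_GFR·GFR·C, µmol/min."""
    if not 0 <= f_GFR <= 1:
        raise ValueError("f_GFR must be in [0, 1]")
    return f_GFR * GFR * C_plasma_kidney


# --------------------------------------------------------------------------
# Model definition


@dataclass
class ModelDefinition:
    """Assembled whole-body ODE system for one species x compound.

    Provides the right-hand side ``rhs(t, y, infusion_rate)``, the
    steady-state initial condition, the state-name index, and a
    human-readable JSON export of states and fluxes for audit.
    """

    species: SpeciesPhysiology
    compound: CompoundProperties
    organ_names: list[str]
    organs: list[OrganPhysiology]
    fcrn_knockout: bool
    rates: EndosomalRates
    igg: EndogenousIgGPool
    igg_ss: IgGSteadyState
    pool: IgGPoolPhysiology
    pool_coeff: TwoPoreCoefficients
    coeffs: list[TwoPoreCoefficients]
    # per-organ arrays (aligned with organ_names)
    V_pls: np.ndarray
    V_int: np.ndarray
    V_endo: np.ndarray
    Q_pls: np.ndarray
    L: np.ndarray
    A_conv: np.ndarray
    B_diff: np.ndarray
    k_up_eff: np.ndarray
    index: dict[str, int] = field(default_factory=dict)

    # --- layout ----------------------------------------------------------

    def _build_index(self) -> None:
        names: list[str] = []
        for block in ("plasma", "interstitial", "endosomal", "endosomal_fcrn_complex", "cellular"):
            names += [f"{block}:{o}" for o in self.organ_names]
        names += ["plasma:arterial", "plasma:venous", "plasma:portal"]
        names += ["igg:plasma", "igg:interstitial", "igg:endosomal", "igg:fcrn_complex"]
        names += ["fcrn:free"]
        names += ["cumulative:catabolism", "cumulative:renal", "cumulative:internalized"]
        if self.compound.target is not None:
            names += ["target:free", "target:complex"]
        self.index = {n: i for i, n in enumerate(names)}

    @property
    def n_organs(self) -> int:
        return len(self.organ_names)

    @property
    def n_states(self) -> int:
        return len(self.index)

    @property
    def state_names(self) -> list[str]:
        return list(self.index)

    # --- cached topology --------------------------------------------------

    def _prepare(self) -> None:
        n = self.n_organs
        self._i_pls = slice(0, n)
        self._i_int = slice(n, 2 * n)
        self._i_ef = slice(2 * n, 3 * n)
        self._i_ec = slice(3 * n, 4 * n)
        self._i_art = self.index["plasma:arterial"]
        self._i_ven = self.index["plasma:venous"]
        self._i_por = self.index["plasma:portal"]
        self._i_igg = self.index["igg:plasma"]
        self._i_fcrn = self.index["fcrn:free"]
        self._i_cat = self.index["cumulative:catabolism"]
        self._i_ren = self.index["cumulative:renal"]
        self._i_itn = self.index["cumulative:internalized"]
        self._lung = self.organ_names.index("lung")
        self._liver = self.organ_names.index("liver")
        self._kidney = self.organ_names.index("kidney")
        self._tumor = self.organ_names.index("tumor") if "tumor" in self.organ_names else None
        self._portal_idx = np.array(
            [self.organ_names.index(o) for o in self.species.portal_organs], dtype=int
        )
        venous_idx = [
            i for i in range(n)
            if i != self._lung and i not in set(self._portal_idx) and i != self._liver
        ]
        self._venous_idx = np.array(venous_idx, dtype=int)
        hct = self.species.HCT
        self._V_art = self.species.blood_pools["arterial"] * (1 - hct)
        self._V_ven = self.species.blood_pools["venous"] * (1 - hct)
        self._V_por = self.species.blood_pools["portal"] * (1 - hct)
        self._CO_pls = self.Q_pls[self._lung]
        self._Q_portal_out = float(
            np.sum(self.Q_pls[self._portal_idx] - self.L[self._portal_idx])
        )
        self._V_endo_tot = float(np.sum(self.V_endo))
        self._CL_ren = (
            self.compound.f_GFR * self.species.GFR if self.compound.f_GFR is not None else 0.0
        )
        self._k_cl = self.rates.k_up - self.rates.k_rec
        # endosomal clearance is tied to uptake: no uptake, no catabolism
        self._k_cl_eff = 0.0 if self.compound.no_endosomal_uptake else self._k_cl
        self._kass_drug = self.compound.fcrn.k_ass
        self._kd_drug = self.compound.fcrn.Kd_acidic
        self._kass_igg = self.rates_kass_igg
        self._L_tot = float(np.sum(self.L))
        # IgG pool coefficient bilinear form
        self._A_pool = self.pool_coeff.convective
        self._B_pool = self.pool_coeff.diffusive

    # --- initial condition ------------------------------------------------

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        ss = self.igg_ss
        y0[self._i_igg] = ss.C_plasma * self.pool.V_plasma
        y0[self.index["igg:interstitial"]] = ss.C_interstitial * self.pool.V_int
        y0[self.index["igg:endosomal"]] = ss.C_endo_free * self._V_endo_tot
        y0[self.index["igg:fcrn_complex"]] = ss.C_complex * self._V_endo_tot
        y0[self._i_fcrn] = ss.C_fcrn_free * self._V_endo_tot
        if self.compound.target is not None and self._tumor is not None:
            v_int_tum = self.V_int[self._tumor]
            y0[self.index["target:free"]] = self.compound.target.baseline * v_int_tum
        return y0

    # --- right-hand side ---------------------------------------------------

    def rhs(self, t: float, y: np.ndarray, infusion_rate: float = 0.0) -> np.ndarray:
        dy = np.zeros_like(y)
        n = self.n_organs
        fu = self.compound.geometry.f_u
        kiv = self.compound.geometry.K_iv

        C_v = y[self._i_pls] / self.V_pls
        C_i = y[self._i_int] / self.V_int
        C_ef = y[self._i_ef] / self.V_endo
        C_ec = y[self._i_ec] / self.V_endo
        C_art = y[self._i_art] / self._V_art
        C_ven = y[self._i_ven] / self._V_ven
        C_por = y[self._i_por] / self._V_por
        C_R = 0.0 if self.fcrn_knockout else y[self._i_fcrn] / self._V_endo_tot

        # --- blood circulation ---
        inflow = self.Q_pls * C_art
        inflow[self._lung] = self._CO_pls * C_ven
        inflow[self._liver] = self.Q_pls[self._liver] * C_art + self._Q_portal_out * C_por
        Q_out = self.Q_pls - self.L
        Q_out[self._liver] = self.Q_pls[self._liver] + self._Q_portal_out - self.L[self._liver]
        outflow = Q_out * C_v

        # --- two-pore exchange, lymph, endosomal cycle ---
        J_vi = fu * (self.A_conv * C_v + self.B_diff * (C_v - C_i / kiv))
        lymph = self.L * C_i
        uptake = self.k_up_eff * self.V_endo * C_v
        recycle = self.rates.k_rec * self.V_endo * C_ec
        netb = self._kass_drug * (C_ef * C_R - self._kd_drug * C_ec) * self.V_endo
        catab = self._k_cl_eff * self.V_endo * C_ef

        dy[self._i_pls] = inflow - outflow - J_vi - uptake + recycle
        dy[self._i_int] = J_vi - lymph
        dy[self._i_ef] = uptake - catab - netb
        dy[self._i_ec] = netb - recycle

        # renal filtration from kidney plasma (kidney plasma state index == organ index)
        renal = self._CL_ren * C_v[self._kidney]
        dy[self._kidney] -= renal
        dy[self._i_ren] = renal
        dy[self._i_cat] = float(np.sum(catab))

        # --- blood pools ---
        dy[self._i_art] = (self._CO_pls - self.L[self._lung]) * C_v[self._lung] \
            - self._CO_pls * C_art
        dy[self._i_ven] = (
            float(np.sum(outflow[self._venous_idx]))
            + outflow[self._liver]
            + float(np.sum(lymph))
            + infusion_rate
            - self._CO_pls * C_ven
        )
        dy[self._i_por] = float(np.sum(outflow[self._portal_idx])) - self._Q_portal_out * C_por

        # --- endogenous IgG pool ---
        Cg_p = y[self._i_igg] / self.pool.V_plasma
        Cg_i = y[self.index["igg:interstitial"]] / self.pool.V_int
        Cg_e = y[self.index["igg:endosomal"]] / self._V_endo_tot
        Cg_c = y[self.index["igg:fcrn_complex"]] / self._V_endo_tot
        Jvi_g = self._A_pool * Cg_p + self._B_pool * (Cg_p - Cg_i / K_IV)
        lymph_g = self._L_tot * Cg_i
        up_g = self.rates.k_up * self._V_endo_tot * Cg_p
        rec_g = self.rates.k_rec * self._V_endo_tot * Cg_c
        netb_g = self._kass_igg * (Cg_e * C_R - self.igg.Kd_acidic * Cg_c) * self._V_endo_tot
        cat_g = self._k_cl * self._V_endo_tot * Cg_e
        dy[self._i_igg] = self.igg_ss.synthesis_rate + rec_g - up_g - Jvi_g + lymph_g
        dy[self.index["igg:interstitial"]] = Jvi_g - lymph_g
        dy[self.index["igg:endosomal"]] = up_g - cat_g - netb_g
        dy[self.index["igg:fcrn_complex"]] = netb_g - rec_g

        # --- pooled free FcRn ---
        if not self.fcrn_knockout:
            dy[self._i_fcrn] = -float(np.sum(netb)) + float(np.sum(recycle)) - netb_g + rec_g

        # --- tumor target ---
        if self.compound.target is not None and self._tumor is not None:
            tgt = self.compound.target
            v_it = self.V_int[self._tumor]
            C_T = y[self.index["target:free"]] / v_it
            C_DT = y[self.index["target:complex"]] / v_it
            netb_t = tgt.k_on * (C_i[self._tumor] * C_T - tgt.Kd * C_DT) * v_it
            intern = tgt.k_int * y[self.index["target:complex"]]
            dy[self.index["target:free"]] = tgt.synthesis * v_it \
                - tgt.k_deg * y[self.index["target:free"]] - netb_t
            dy[self.index["target:complex"]] = netb_t - intern
            dy[n + self._tumor] -= netb_t      # drug leaves tumor interstitial space
            dy[self._i_itn] = intern

        return dy

    # --- bookkeeping --------------------------------------------------------

    def drug_amount_indices(self) -> np.ndarray:
        """Indices of all states carrying drug (for mass balance)."""
        n = self.n_organs
        idx = list(range(0, 4 * n))  # plasma/interstitial/endosomal free+complex
        idx += [self._i_art, self._i_ven, self._i_por]
        if self.compound.target is not None:
            idx += [self.index["target:complex"]]
        return np.array(idx, dtype=int)

    def ledger_indices(self) -> np.ndarray:
        return np.array([self._i_cat, self._i_ren, self._i_itn], dtype=int)

    def total_fcrn_amount(self, y: np.ndarray) -> float:
        """Free + IgG-bound + drug-bound FcRn amount in µmol."""
        n = self.n_organs
        return float(
            y[self._i_fcrn]
            + y[self.index["igg:fcrn_complex"]]
            + np.sum(y[3 * n:4 * n])
        )

    def export_definition(self) -> str:
        """JSON listing of states and registered fluxes for audit."""
        fluxes = []
        for i, o in enumerate(self.organ_names):
            fluxes.append({"flux": "two_pore", "source": f"plasma:{o}",
                           "sink": f"interstitial:{o}",
                           "convective_l_min": self.A_conv[i],
                           "diffusive_l_min": self.B_diff[i]})
            fluxes.append({"flux": "lymph", "source": f"interstitial:{o}",
                           "sink": "plasma:venous", "L_l_min": self.L[i]})
            fluxes.append({"flux": "endosomal_uptake", "source": f"plasma:{o}",
                           "sink": f"endosomal:{o}",
                           "k_up_V_l_min": self.k_up_eff[i] * self.V_endo[i]})
            fluxes.append({"flux": "fcrn_recycling",
                           "source": f"endosomal_fcrn_complex:{o}",
                           "sink": f"plasma:{o}",
                           "k_rec_V_l_min": self.rates.k_rec * self.V_endo[i]})
            fluxes.append({"flux": "endosomal_clearance", "source": f"endosomal:{o}",
                           "sink": "cumulative:catabolism",
                           "k_cl_V_l_min": self._k_cl * self.V_endo[i]})
        if self._CL_ren > 0:
            fluxes.append({"flux": "renal", "source": "plasma:kidney",
                           "sink": "cumulative:renal", "CL_l_min": self._CL_ren})
        if self.compound.target is not None:
            fluxes.append({"flux": "target_internalization", "source": "target:complex",
                           "sink": "cumulative:internalized",
                           "k_int_per_min": self.compound.target.k_int})
        return json.dumps(
            {
                "species": self.species.name,
                "compound": self.compound.name,
                "states": self.state_names,
                "fluxes": fluxes,
            },
            indent=2,
        )


# --------------------------------------------------------------------------
# Builders


def _assemble_pool(
    species: SpeciesPhysiology, organs: list[OrganPhysiology]
) -> IgGPoolPhysiology:
    """IgG pool lumped over the model's organ list (tumor included if present)."""
    S_each = [species.capillary_surface_area(o) for o in organs]
    S_tot = sum(S_each)
    return IgGPoolPhysiology(
        V_plasma=sum(species.organ_plasma_volume(o) for o in organs)
        + sum(species.blood_pools.values()) * (1 - species.HCT),
        V_int=sum(o.f_int * o.V_org for o in organs),
        V_endo=sum(species.endosomal_volume(o) for o in organs),
        S=S_tot,
        L=sum(species.lymph_flow(o) for o in organs),
        J_iso=sum(species.recirculation_flow(o) for o in organs),
        Lp=sum(o.Lp * s for o, s in zip(organs, S_each)) / S_tot,
    )


def build_model(
    species: SpeciesPhysiology,
    compound: CompoundProperties,
    *,
    tumor: TumorOrganParams | None = None,
    fcrn_knockout: bool = False,
    igg: EndogenousIgGPool | None = None,
    rates: EndosomalRates | None = None,
) -> ModelDefinition:
    """Assemble the complete whole-body model.

    ``igg`` and ``rates`` default to the bundled species FcRn parameters.
    With ``fcrn_knockout`` the total FcRn amount is zero and every
    endosomally taken-up molecule is degraded.
    """
    from .config import load_fcrn_defaults

    defaults_rates, igg_by_species, k_ass = load_fcrn_defaults()
    if rates is None:
        rates = defaults_rates
    if igg is None:
        igg = igg_by_species[species.name]
    if fcrn_knockout:
        igg = EndogenousIgGPool(
            C_igg_plasma=igg.C_igg_plasma,
            Kd_acidic=igg.Kd_acidic,
            C_fcrn_free=0.0,
            Kd_neutral=igg.Kd_neutral,
        )

    organs = list(species.organs.values())
    if tumor is not None:
        organs.append(tumor.as_organ())
    elif compound.target is not None:
        raise ValueError("a target-binding compound requires the tumor organ")
    organ_names = [o.name for o in organs]

    n = len(organs)
    V_pls = np.array([species.organ_plasma_volume(o) for o in organs])
    V_int = np.array([o.f_int * o.V_org for o in organs])
    V_endo = np.array([species.endosomal_volume(o) for o in organs])
    Q_pls = np.array([o.Q_blood * (1 - species.HCT) for o in organs])
    if tumor is not None:
        # lung carries the total cardiac output including the tumor supply
        Q_pls[organ_names.index("lung")] += Q_pls[organ_names.index("tumor")]
    L = np.array([species.lymph_flow(o) for o in organs])
    J_iso = np.array([species.recirculation_flow(o) for o in organs])

    coeffs = [
        organ_coefficients(
            o.name,
            compound.geometry.a_e,
            o.Lp,
            o.alpha_L,
            o.r_S,
            o.r_L,
            species.capillary_surface_area(o),
            L[i],
            J_iso[i],
        )
        for i, o in enumerate(organs)
    ]
    A_conv = np.array([c.convective for c in coeffs])
    B_diff = np.array([c.diffusive for c in coeffs])

    k_up_eff = np.full(n, 0.0 if compound.no_endosomal_uptake else rates.k_up)

    pool = _assemble_pool(species, organs)
    ss = igg_steady_state(pool, igg, rates, k_ass)

    model = ModelDefinition(
        species=species,
        compound=compound,
        organ_names=organ_names,
        organs=organs,
        fcrn_knockout=fcrn_knockout,
        rates=rates,
        igg=igg,
        igg_ss=ss,
        pool=pool,
        pool_coeff=pool_coefficients(pool),
        coeffs=coeffs,
        V_pls=V_pls,
        V_int=V_int,
        V_endo=V_endo,
        Q_pls=Q_pls,
        L=L,
        A_conv=A_conv,
        B_diff=B_diff,
        k_up_eff=k_up_eff,
    )
    model.rates_kass_igg = k_ass
    model._build_index()
    model._prepare()
    return model


def add_tumor_organ(
    species: SpeciesPhysiology,
    compound: CompoundProperties,
    tumor: TumorOrganParams,
    **kwargs,
) -> ModelDefinition:
    """Convenience wrapper: build the whole-body model extended by a tumor."""
    return build_model(species, compound, tumor=tumor, **kwargs)
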