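"""Endosomal uptake, FcRn binding, recycling and catabolic clearance.

Drug (and endogenous IgG) is taken up from plasma into the endosomal
space of the vascular endothelium by fluid-phase pinocytosis (first
order in plasma concentration, rate constant k_up).  Inside the acidic
endosome it binds the neonatal Fc receptor by mass action; the
FcRn-bound fraction is recycled back to plasma (rate constant k_rec)
while unbound material is degraded with the net rate constant
k_up − k_rec.  Endogenous IgG competes with the drug for one pooled
free-FcRn concentration distributed over the total endosomal volume.

The drug-free steady state of the endogenous IgG/FcRn pool is solved
algebraically here and used as the simulation initial condition.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import KD_NEUTRAL_IGG, K_IV
from .physiology import IgGPoolPhysiology
from .twopore import TwoPoreCoefficients, organ_coefficients

__all__ = [
    "FcRnBindingParams",
    "EndosomalRates",
    "EndogenousIgGPool",
    "IgGSteadyState",
    "uptake_flux",
    "recycling_flux",
    "endosomal_clearance",
    "binding_rate",
    "igg_steady_state",
    "pool_coefficients",
]

IGG_RADIUS_NM = 5.34  # endogenous IgG treated as a standard antibody


@dataclass(frozen=True)
class FcRnBindingParams:
    """Mass-action FcRn binding: k_ass (l/µmol/min), Kd values (µmol/l)."""

    k_ass: float
    Kd_acidic: float
    Kd_neutral: float = 999_999.0

    def __post_init__(self) -> None:
        if min(self.k_ass, self.Kd_acidic, self.Kd_neutral) <= 0:
            raise ValueError("FcRn binding parameters must be positive")


@dataclass(frozen=True)
class EndosomalRates:
    """Endosomal uptake/recycling rate constants (1/min) and routing fractions."""

    k_up: float
    k_rec: float
    f_vas_up: float = 1.0
    f_vas_rec: float = 1.0

    def __post_init__(self) -> None:
        if self.k_rec < 0 or self.k_up < self.k_rec:
            raise ValueError("require k_up >= k_rec >= 0 (nonnegative endosomal clearance)")
        for f in (self.f_vas_up, self.f_vas_rec):
            if not 0 <= f <= 1:
                raise ValueError("routing fractions must be in [0, 1]")


@dataclass(frozen=True)
class EndogenousIgGPool:
    """Species parameters of the lumped endogenous IgG/FcRn sub-model."""

    C_igg_plasma: float       # µmol/l, homeostatic plasma IgG
    Kd_acidic: float          # µmol/l
    C_fcrn_free: float        # µmol/l, fitted free endosomal FcRn
    Kd_neutral: float = KD_NEUTRAL_IGG


def uptake_flux(
    C_plasma: float, C_interstitial: float, V_endo: float, rates: EndosomalRates
) -> tuple[float, float]:
    """Endosomal uptake (µmol/min) from plasma and interstitial space.

    With the standard routing f_vas_up = 1 the interstitial contribution
    is exactly zero, restricting extravasation to the two-pore pathway.
    """
    if V_endo < 0:
        raise ValueError("endosomal volume must be nonnegative")
    from_plasma = rates.f_vas_up * rates.k_up * V_endo * C_plasma
    from_interstitial = (1.0 - rates.f_vas_up) * rates.k_up * V_endo * C_interstitial
    return from_plasma, from_interstitial


def recycling_flux(
    C_complex_endo: float, V_endo: float, rates: EndosomalRates
) -> tuple[float, float]:
    """FcRn-complex recycling (µmol/min) to plasma and interstitial space."""
    if V_endo < 0:
        raise ValueError("endosomal volume must be nonnegative")
    total = rates.k_rec * V_endo * C_complex_endo
    return rates.f_vas_rec * total, (1.0 - rates.f_vas_rec) * total


def endosomal_clearance(C_free_endo: float, V_endo: float, rates: EndosomalRates) -> float:
    """Degradation of FcRn-unbound endosomal material, (k_up − k_rec)·V·C in µmol/min."""
    return (rates.k_up - rates.k_rec) * V_endo * C_free_endo


def binding_rate(
    C_free: float, C_fcrn: float, C_complex: float, params: FcRnBindingParams, *, acidic: bool = True
) -> float:
    """Net mass-action association rate in µmol/l/min.

    k_ass·C_free·C_FcRn − Kd·k_ass·C_complex; zero at the equilibrium
    C_free·C_FcRn = Kd·C_complex.
    """
    kd = params.Kd_acidic if acidic else params.Kd_neutral
    return params.k_ass * C_free * C_fcrn - kd * params.k_ass * C_complex


def pool_coefficients(pool: IgGPoolPhysiology, a_e_nm: float = IGG_RADIUS_NM) -> TwoPoreCoefficients:
    """Two-pore coefficients of the lumped IgG pool 'organ'."""
    return organ_coefficients(
        "igg_pool",
        a_e_nm,
        pool.Lp,
        pool.alpha_L,
        pool.r_S,
        pool.r_L,
        pool.S,
        pool.L,
        pool.J_iso,
    )


@dataclass(frozen=True)
class IgGSteadyState:
    """Drug-free stationary state of the endogenous IgG/FcRn pool.

    Concentrations in µmol/l (endosomal species over the pooled endosomal
    volume), the zero-order synthesis rate in µmol/min, and the total
    FcRn concentration implied by the fitted free concentration.
    """

    C_plasma: float
    C_interstitial: float
    C_endo_free: float
    C_complex: float
    C_fcrn_free: float
    C_fcrn_total: float
    synthesis_rate: float


def igg_steady_state(
    pool: IgGPoolPhysiology,
    igg: EndogenousIgGPool,
    rates: EndosomalRates,
    k_ass: float,
    K_iv: float = K_IV,
) -> IgGSteadyState:
    """Solve the drug-free balance equations of the IgG/FcRn pool.

    Given the homeostatic plasma IgG concentration and the fitted free
    endosomal FcRn concentration, the remaining unknowns follow
    algebraically because the drug-free system is linear at fixed free
    FcRn:

    * endosomal complex balance: net binding = recycling,
    * endosomal free-IgG balance: uptake = clearance + net binding,
    * interstitial balance: two-pore influx = lymph return,
    * plasma balance: synthesis = catabolism (all other terms cancel).

    The total FcRn concentration is the free value plus the equilibrium
    complex; forward simulation from the returned state leaves every
    state variable unchanged.
    """
    C_p = igg.C_igg_plasma
    C_R = igg.C_fcrn_free
    if C_p < 0 or C_R < 0:
        raise ValueError("concentrations must be nonnegative")

    # Endosomal cycling.  With C_R = 0 (FcRn knockout) the complex is 0.
    denom_c = rates.k_rec + k_ass * igg.Kd_acidic
    ratio = k_ass * C_R / denom_c          # complex per unit free IgG
    k_cl = rates.k_up - rates.k_rec
    if rates.k_up == 0.0:
        C_e = 0.0
        C_c = 0.0
    else:
        C_e = rates.k_up * C_p / (k_cl + rates.k_rec * ratio)
        C_c = ratio * C_e
    if min(C_e, C_c) < 0:
        raise ValueError("infeasible parameter set: negative steady-state concentration")

    # Interstitial space: A·C_p + B·(C_p − C_i/K_iv) = L·C_i
    coeff = pool_coefficients(pool)
    A = coeff.convective
    B = coeff.diffusive
    C_i = (A + B) * C_p / (pool.L + B / K_iv) if pool.L + B / K_iv > 0 else 0.0

    synthesis = k_cl * pool.V_endo * C_e   # equals total catabolism
    return IgGSteadyState(
        C_plasma=C_p,
        C_interstitial=C_i,
        C_endo_free=C_e,
        C_complex=C_c,
        C_fcrn_free=C_R,
        C_fcrn_total=C_R + C_c,
        synthesis_rate=synthesis,
    )
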