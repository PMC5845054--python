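"""Two-pore transcapillary exchange physics.

The capillary wall is modelled as a membrane perforated by two classes of
cylindrical pores (small and large).  A solute of hydrodynamic radius
``a_e`` crosses by convection with the transcapillary fluid flows and by
restricted diffusion, with pore-class-specific reflection coefficients
(sigma), restricted-diffusion factors (xi) and permeability-surface-area
products (PS).  The net plasma-to-interstitial drug flux combines the
convective and diffusive contributions of both pore classes through
Peclet-number weighting.

All functions are pure; per-organ coefficient bundles are assembled by
:func:`organ_coefficients` and consumed by the ODE assembly layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import ETA_WATER, K_IV, N_AVOGADRO, NM_TO_CM, RT

__all__ = [
    "SoluteGeometry",
    "TwoPoreCoefficients",
    "stokes_einstein_D",
    "reflection_sigma",
    "xi_restricted_diffusion",
    "pore_area_ratio",
    "permeability",
    "fluid_flows",
    "peclet",
    "peclet_weight",
    "transcapillary_flux",
    "organ_coefficients",
    "coefficient_table",
]


@dataclass(frozen=True)
class SoluteGeometry:
    """Size and partitioning of a solute.

    Parameters
    ----------
    a_e : float
        Hydrodynamic radius in nm.
    f_u : float
        Fraction unbound in plasma (1 for all bundled compounds).
    K_iv : float
        Interstitial/plasma partition coefficient.
    """

    a_e: float
    f_u: float = 1.0
    K_iv: float = K_IV

    def __post_init__(self) -> None:
        if self.a_e <= 0:
            raise ValueError("hydrodynamic radius must be positive")
        if not 0 < self.f_u <= 1:
            raise ValueError("fraction unbound must be in (0, 1]")
        if self.K_iv <= 0:
            raise ValueError("partition coefficient must be positive")


def stokes_einstein_D(a_e_nm: float) -> float:
    """Free diffusion coefficient in cm^2/min from the Stokes-Einstein relation.

    D = RT / (6 pi N_a a_e eta) with RT and eta fixed at 37 degC.
    """
    if a_e_nm <= 0:
        raise ValueError("hydrodynamic radius must be positive")
    a_cm = a_e_nm * NM_TO_CM
    return RT / (6.0 * math.pi * N_AVOGADRO * a_cm * ETA_WATER)


def reflection_sigma(gamma: float) -> float:
    """Osmotic reflection coefficient for a pore, gamma = a_e / r_pore.

    Clamped to 1 for gamma >= 1: a solute larger than the pore is fully
    rejected and that pathway transmits nothing.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if gamma >= 1.0:
        return 1.0
    one_m = 1.0 - gamma
    num = one_m**2 * (2.0 - one_m**2) * (1.0 - gamma / 3.0)
    den = 1.0 - gamma / 3.0 + 2.0 / 3.0 * gamma**2
    return 1.0 - num / den


def xi_restricted_diffusion(gamma: float) -> float:
    """Restricted-diffusion area factor, clamped to 0 for gamma >= 1."""
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    if gamma >= 1.0:
        return 0.0
    return (1.0 - gamma) ** 4.5 / (1.0 - 0.3956 * gamma + 1.0616 * gamma**2)


def pore_area_ratio(Lp: float, alpha_L: float, r_pore_nm: float, *, large: bool) -> float:
    """Pore cross-section per membrane-thickness-and-surface, A/(L*S) in 1/cm.

    Poiseuille partitioning of the hydraulic conductivity ``Lp``
    (ml/min/N == cm^3/min/N) between the two pore classes: the large-pore
    class carries a fraction ``alpha_L`` of the fluid conductance, the
    small-pore class the complement.
    """
    if r_pore_nm <= 0:
        raise ValueError("pore radius must be positive")
    if not 0 <= alpha_L <= 1:
        raise ValueError("alpha_L must be in [0, 1]")
    if Lp < 0:
        raise ValueError("hydraulic conductivity must be nonnegative")
    frac = alpha_L if large else (1.0 - alpha_L)
    r_cm = r_pore_nm * NM_TO_CM
    return frac * 8.0 * ETA_WATER * Lp / r_cm**2


def permeability(
    D: float, xi: float, area_ratio: float, S_org: float
) -> float:
    """Permeability-surface-area product PS in l/min.

    PS = xi * D * (A / (L S)) * S with D in cm^2/min, the area ratio in
    1/cm and S in cm^2; the cm^3/min result is converted to l/min.
    """
    ps_cm3 = xi * D * area_ratio * S_org
    return ps_cm3 * 1e-3


def fluid_flows(alpha_L: float, L_org: float, J_iso: float) -> tuple[float, float]:
    """Transcapillary fluid flows (J_L, J_S) in l/min.

    The recirculation flow J_iso runs outward through large pores and
    inward through small pores; the lymph flow L splits by alpha.
    J_L + J_S == L exactly.  J_S may be negative (net inward small-pore
    flow) under strong recirculation.
    """
    J_L = J_iso + alpha_L * L_org
    J_S = -J_iso + (1.0 - alpha_L) * L_org
    return J_L, J_S


def peclet(J: float, sigma: float, PS: float) -> float:
    """Peclet number J (1 - sigma) / PS; +inf sentinel when PS == 0."""
    if PS < 0:
        raise ValueError("PS must be nonnegative")
    conv = J * (1.0 - sigma)
    if PS == 0.0:
        return math.inf if conv != 0.0 else 0.0
    return conv / PS


def peclet_weight(Pe: float) -> float:
    """Numerically stable phi(Pe) = Pe / (exp(Pe) - 1), phi(0) = 1.

    Continuous and monotonically decreasing; evaluates without overflow
    for arbitrarily large Pe (asymptotically 0) and handles the infinite
    sentinel returned by :func:`peclet` when PS = 0.
    """
    if math.isinf(Pe):
        return 0.0 if Pe > 0 else math.inf
    if abs(Pe) < 1e-8:
        return 1.0 - Pe / 2.0
    if Pe > 700.0:
        return 0.0
    return Pe / math.expm1(Pe)


@dataclass(frozen=True)
class TwoPoreCoefficients:
    """Per organ x compound coefficients of the two-pore flux law.

    ``convective`` is J_L(1-sigma_L) + J_S(1-sigma_S) (l/min) and
    ``diffusive`` is PS_L*phi(Pe_L) + PS_S*phi(Pe_S) (l/min), so the flux
    is the bilinear form ``f_u * (convective*C_v + diffusive*(C_v - C_i/K_iv))``.
    """

    organ: str
    D: float
    sigma_L: float
    sigma_S: float
    xi_L: float
    xi_S: float
    PS_L: float
    PS_S: float
    J_L: float
    J_S: float
    Pe_L: float
    Pe_S: float

    @property
    def convective(self) -> float:
        return self.J_L * (1.0 - self.sigma_L) + self.J_S * (1.0 - self.sigma_S)

    @property
    def diffusive(self) -> float:
        return self.PS_L * peclet_weight(self.Pe_L) + self.PS_S * peclet_weight(self.Pe_S)


def transcapillary_flux(
    C_v: float,
    C_i: float,
    coeff: TwoPoreCoefficients,
    f_u: float = 1.0,
    K_iv: float = K_IV,
) -> float:
    """Net drug flux plasma -> interstitial space in µmol/min.

    Sum of large- and small-pore convective terms (proportional to the
    plasma concentration) and diffusive terms (proportional to the
    partition-corrected concentration difference), each diffusive term
    weighted by phi(Pe).
    """
    return f_u * (
        coeff.convective * C_v + coeff.diffusive * (C_v - C_i / K_iv)
    )


def organ_coefficients(
    organ_name: str,
    a_e_nm: float,
    Lp: float,
    alpha_L: float,
    r_S_nm: float,
    r_L_nm: float,
    S_org: float,
    L_org: float,
    J_iso: float,
) -> TwoPoreCoefficients:
    """Assemble all two-pore coefficients for one organ and one solute.

    Parameters are the organ's endothelial properties (Lp in ml/min/N,
    radii in nm, surface S in cm^2) and its lymph and recirculation flows
    (l/min); the solute enters through its hydrodynamic radius.
    """
    D = stokes_einstein_D(a_e_nm)
    g_L = a_e_nm / r_L_nm
    g_S = a_e_nm / r_S_nm
    sig_L = reflection_sigma(g_L)
    sig_S = reflection_sigma(g_S)
    xi_L = xi_restricted_diffusion(g_L)
    xi_S = xi_restricted_diffusion(g_S)
    PS_L = permeability(D, xi_L, pore_area_ratio(Lp, alpha_L, r_L_nm, large=True), S_org)
    PS_S = permeability(D, xi_S, pore_area_ratio(Lp, alpha_L, r_S_nm, large=False), S_org)
    J_L, J_S = fluid_flows(alpha_L, L_org, J_iso)
    return TwoPoreCoefficients(
        organ=organ_name,
        D=D,
        sigma_L=sig_L,
        sigma_S=sig_S,
        xi_L=xi_L,
        xi_S=xi_S,
        PS_L=PS_L,
        PS_S=PS_S,
        J_L=J_L,
        J_S=J_S,
        Pe_L=peclet(J_L, sig_L, PS_L),
        Pe_S=peclet(J_S, sig_S, PS_S),
    )


def coefficient_table(species, compound) -> "pandas.DataFrame":  # noqa: F821
    """Per-organ two-pore coefficient table for diagnostics/export.

    Columns mirror the quantities of the flux law: sigma, xi, PS, fluid
    flows, Peclet numbers and the convective/diffusive split.
    """
    import pandas as pd

    rows = []
    for organ in species.organs.values():
        c = organ_coefficients(
            organ.name,
            compound.geometry.a_e,
            organ.Lp,
            organ.alpha_L,
            organ.r_S,
            organ.r_L,
            species.capillary_surface_area(organ),
            species.lymph_flow(organ),
            species.recirculation_flow(organ),
        )
        rows.append(
            {
                "organ": c.organ,
                "D_cm2_min": c.D,
                "sigma_L": c.sigma_L,
                "sigma_S": c.sigma_S,
                "xi_L": c.xi_L,
                "xi_S": c.xi_S,
                "PS_L_l_min": c.PS_L,
                "PS_S_l_min": c.PS_S,
                "J_L_l_min": c.J_L,
                "J_S_l_min": c.J_S,
                "Pe_L": c.Pe_L,
                "Pe_S": c.Pe_S,
                "convective_l_min": c.convective,
                "diffusive_l_min": c.diffusive,
            }
        )
    return pd.DataFrame(rows).set_index("organ")
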