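"""Two-pore physics: reflection/diffusion factors, permeabilities, flux law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proteinpbpk.twopore import (
    SoluteGeometry,
    fluid_flows,
    organ_coefficients,
    peclet,
    peclet_weight,
    permeability,
    pore_area_ratio,
    reflection_sigma,
    stokes_einstein_D,
    transcapillary_flux,
    xi_restricted_diffusion,
)


def sigma_unfactored(g: float) -> float:
    """Independent single-expression evaluation of the reflection coefficient."""
    return 1 - ((1 - g) ** 2 * (2 - (1 - g) ** 2) * (1 - g / 3)) / (1 - g / 3 + 2 / 3 * g**2)


class TestStokesEinstein:
    def test_inulin_value(self):
        # direct evaluation with the fixed 37 degC constants
        assert stokes_einstein_D(1.39) == pytest.approx(1.398e-4, rel=1e-3)

    def test_inverse_proportionality(self):
        assert stokes_einstein_D(2.0) == pytest.approx(stokes_einstein_D(1.0) / 2.0, rel=1e-12)

    def test_antibody_inulin_ratio(self):
        assert stokes_einstein_D(5.34) / stokes_einstein_D(1.39) == pytest.approx(
            1.39 / 5.34, rel=1e-12
        )

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            stokes_einstein_D(0.0)


class TestReflectionAndDiffusionFactors:
    @pytest.mark.parametrize(
        "gamma, expected",
        [
            (0.0, 0.0),
            (1.0, 1.0),
            (1.5, 1.0),               # clamp: solute larger than pore
            (5.34 / 33.0, sigma_unfactored(5.34 / 33.0)),   # antibody, liver large pores
        ],
    )
    def test_sigma_values(self, gamma, expected):
        assert reflection_sigma(gamma) == pytest.approx(expected, abs=1e-12)

    def test_sigma_antibody_liver_magnitude(self):
        assert reflection_sigma(5.34 / 33.0) == pytest.approx(0.105, abs=0.002)

    @pytest.mark.parametrize(
        "gamma, expected",
        [
            (0.0, 1.0),
            (1.0, 0.0),
            (2.0, 0.0),
            (1.39 / 4.5, (1 - 1.39 / 4.5) ** 4.5
             / (1 - 0.3956 * 1.39 / 4.5 + 1.0616 * (1.39 / 4.5) ** 2)),
        ],
    )
    def test_xi_values(self, gamma, expected):
        assert xi_restricted_diffusion(gamma) == pytest.approx(expected, abs=1e-12)

    def test_xi_inulin_small_pores_magnitude(self):
        assert xi_restricted_diffusion(1.39 / 4.5) == pytest.approx(0.19, abs=0.01)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=2.0))
    def test_sigma_in_unit_interval(self, gamma):
        assert 0.0 <= reflection_sigma(gamma) <= 1.0

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=2.0))
    def test_xi_in_unit_interval(self, gamma):
        assert 0.0 <= xi_restricted_diffusion(gamma) <= 1.0

    def test_sigma_nondecreasing_xi_nonincreasing(self):
        g = np.linspace(0.0, 1.2, 500)
        sig = np.array([reflection_sigma(x) for x in g])
        xi = np.array([xi_restricted_diffusion(x) for x in g])
        assert np.all(np.diff(sig) >= -1e-12)
        assert np.all(np.diff(xi) <= 1e-12)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            reflection_sigma(-0.1)
        with pytest.raises(ValueError):
            xi_restricted_diffusion(-0.1)


class TestPoreAreaRatioAndPermeability:
    def test_muscle_small_pores(self):
        # (1-0.05)*8*eta*Lp/r_S^2 with muscle Lp
        ratio = pore_area_ratio(3.24e-4, 0.05, 4.5, large=False)
        assert ratio == pytest.approx(14.2, rel=0.01)

    def test_alpha_zero_kills_large_pores(self):
        assert pore_area_ratio(1e-3, 0.0, 25.0, large=True) == 0.0

    def test_linear_in_Lp(self):
        r1 = pore_area_ratio(1e-3, 0.05, 4.5, large=False)
        r2 = pore_area_ratio(2e-3, 0.05, 4.5, large=False)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_antibody_small_pore_PS_zero(self):
        # antibody radius exceeds the continuous-endothelium small pores
        xi = xi_restricted_diffusion(5.34 / 4.5)
        ps = permeability(stokes_einstein_D(5.34), xi,
                          pore_area_ratio(3.24e-4, 0.05, 4.5, large=False), 100.0)
        assert ps == 0.0

    def test_xi_one_limit(self):
        D, ar, S = 1.4e-4, 14.0, 100.0
        assert permeability(D, 1.0, ar, S) == pytest.approx(D * ar * S * 1e-3, rel=1e-12)

    def test_monotone_in_radius(self):
        """Increasing solute radius never increases PS nor decreases sigma."""
        radii = np.linspace(0.5, 10.0, 40)
        last_ps, last_sig = np.inf, -1.0
        for a in radii:
            c = organ_coefficients("muscle", a, 3.24e-4, 0.05, 4.5, 25.0, 100.0, 1e-6, 5e-7)
            ps = c.PS_L + c.PS_S
            assert ps <= last_ps + 1e-15
            assert c.sigma_L >= last_sig - 1e-15
            last_ps, last_sig = ps, c.sigma_L


class TestFluidFlowsAndPeclet:
    def test_split_and_conservation(self):
        J_L, J_S = fluid_flows(0.05, 1e-4, 0.0)
        assert J_L == pytest.approx(0.05e-4)
        assert J_S == pytest.approx(0.95e-4)
        for jiso in (0.0, 3e-5, 9.6e-5):
            J_L, J_S = fluid_flows(0.05, 1e-4, jiso)
            assert J_L + J_S == pytest.approx(1e-4, rel=1e-14)

    def test_peclet_limits(self):
        assert peclet(0.0, 0.5, 1e-6) == 0.0
        assert peclet(1e-4, 1.0, 1e-6) == 0.0
        assert peclet(1e-4, 0.5, 0.0) == math.inf

    def test_phi_edge_cases(self):
        assert peclet_weight(0.0) == 1.0
        assert peclet_weight(1e-12) == pytest.approx(1.0, abs=1e-9)
        assert peclet_weight(700.0) == pytest.approx(0.0, abs=1e-300)
        assert peclet_weight(1e6) == 0.0        # no overflow
        assert peclet_weight(math.inf) == 0.0   # PS = 0 sentinel -> no diffusive term

    def test_phi_continuous_and_decreasing(self):
        x = np.linspace(-5, 50, 2000)
        vals = np.array([peclet_weight(v) for v in x])
        assert np.all(np.diff(vals) < 0)
        # continuity across 0
        assert abs(peclet_weight(1e-9) - peclet_weight(-1e-9)) < 1e-8


class TestFluxLaw:
    def _random_coeffs(self, rng):
        return organ_coefficients(
            "x",
            float(rng.uniform(0.5, 8.0)),
            float(rng.uniform(1e-6, 1e-2)),
            float(rng.uniform(0.0, 0.9)),
            4.5, 25.0,
            float(rng.uniform(10, 1000)),
            float(rng.uniform(1e-7, 1e-4)),
            float(rng.uniform(0.0, 5e-5)),
        )

    def test_zero_concentrations_zero_flux(self):
        rng = np.random.default_rng(0)
        c = self._random_coeffs(rng)
        assert transcapillary_flux(0.0, 0.0, c) == 0.0

    def test_impermeable_wall(self):
        c = organ_coefficients("x", 50.0, 1e-3, 0.05, 4.5, 25.0, 100.0, 1e-5, 0.0)
        assert c.sigma_L == 1.0 and c.sigma_S == 1.0
        assert c.PS_L == 0.0 and c.PS_S == 0.0
        assert transcapillary_flux(3.0, 1.0, c) == 0.0

    def test_against_unfactored_oracle(self):
        """Term-by-term brute-force evaluation of the four summands."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            c = self._random_coeffs(rng)
            C_v = float(rng.uniform(0, 10))
            C_i = float(rng.uniform(0, 10))
            fu, kiv = 1.0, 0.96

            def phi(pe):
                if pe > 700:
                    return 0.0
                return pe / math.expm1(pe) if pe != 0 else 1.0

            terms = 0.0
            terms += c.J_L * (1 - c.sigma_L) * C_v
            if c.PS_L > 0:
                terms += c.PS_L * (C_v - C_i / kiv) * phi(c.J_L * (1 - c.sigma_L) / c.PS_L)
            terms += c.J_S * (1 - c.sigma_S) * C_v
            if c.PS_S > 0:
                terms += c.PS_S * (C_v - C_i / kiv) * phi(c.J_S * (1 - c.sigma_S) / c.PS_S)
            expected = fu * terms
            assert transcapillary_flux(C_v, C_i, c, fu, kiv) == pytest.approx(
                expected, rel=1e-12, abs=1e-300
            )


class TestSoluteGeometry:
    def test_validation(self):
        with pytest.raises(ValueError):
            SoluteGeometry(a_e=-1.0)
        with pytest.raises(ValueError):
            SoluteGeometry(a_e=1.0, f_u=0.0)
        g = SoluteGeometry(a_e=5.34)
        assert g.f_u == 1.0 and g.K_iv == 0.96
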