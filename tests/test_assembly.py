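"""Whole-body ODE assembly: topology, mass balance, extensions, oracle."""

import json
import math

import numpy as np
import pytest
from scipy.integrate import odeint

from proteinpbpk.assembly import (
    CompoundProperties,
    DoseEvent,
    TargetBindingParams,
    build_model,
    load_tumor_params,
    lymph_return_flux,
    renal_clearance_flux,
)
from proteinpbpk.config import load_compound
from proteinpbpk.fcrn import FcRnBindingParams
from proteinpbpk.fixtures import make_fixture
from proteinpbpk.physiology import load_species
from proteinpbpk.simulate import simulate
from proteinpbpk.twopore import SoluteGeometry

from conftest import make_reduced_species


class TestElementaryFluxes:
    @pytest.mark.parametrize("C_i, L, expected", [(0.0, 1e-4, 0.0), (2.0, 0.0, 0.0),
                                                  (2.0, 1e-4, 2e-4)])
    def test_lymph_return(self, C_i, L, expected):
        assert lymph_return_flux(C_i, L) == pytest.approx(expected)

    def test_renal_clearance_values(self):
        # inulin in rat: f_GFR = 1, GFR = 1.31 ml/min
        assert renal_clearance_flux(1.0, 1.0, 1.31e-3) == pytest.approx(1.31e-3)
        # domain antibody in mouse: f_GFR = 0.24, GFR = 0.28 ml/min
        assert renal_clearance_flux(1.0, 0.24, 0.28e-3) == pytest.approx(6.72e-5)
        assert renal_clearance_flux(5.0, 0.0, 1e-3) == 0.0
        with pytest.raises(ValueError):
            renal_clearance_flux(1.0, 1.5, 1e-3)


class TestModelStructure:
    def test_state_count(self, mouse):
        model = build_model(mouse, load_compound("antibody_7e3"))
        n = model.n_organs
        assert n == 15
        # 5 blocks per organ + 3 blood pools + 4 IgG + FcRn + 3 ledgers
        assert model.n_states == 5 * n + 3 + 4 + 1 + 3

    def test_tumor_adds_organ_and_target_states(self, mouse):
        model = build_model(mouse, load_compound("bay_79_4620"), tumor=load_tumor_params())
        assert "tumor" in model.organ_names
        assert model.n_states == 5 * 16 + 3 + 4 + 1 + 3 + 2

    def test_target_without_tumor_rejected(self, mouse):
        with pytest.raises(ValueError):
            build_model(mouse, load_compound("bay_79_4620"))

    def test_export_definition_json(self, mouse):
        model = build_model(mouse, load_compound("domain_antibody"))
        doc = json.loads(model.export_definition())
        assert set(doc) == {"species", "compound", "states", "fluxes"}
        kinds = {f["flux"] for f in doc["fluxes"]}
        assert {"two_pore", "lymph", "endosomal_uptake", "fcrn_recycling", "renal"} <= kinds
        assert len(doc["states"]) == model.n_states


class TestConservation:
    def test_impermeable_compound_confined_to_blood(self, mouse, inert_compound):
        """sigma = 1, PS = 0 everywhere, no uptake, no renal: the dose stays
        in the plasma/blood pools and the total amount is constant."""
        model = build_model(mouse, inert_compound)
        assert np.all(model.A_conv == 0.0) and np.all(model.B_diff == 0.0)
        res = simulate(model, [DoseEvent(0.0, 1e-3)], t_end=2880.0, n_points=60)
        total = res.total_drug_amount()
        assert np.max(np.abs(total - 1e-3)) < 1e-9
        n = model.n_organs
        # nothing outside the vascular space
        assert np.max(np.abs(res.states[n:4 * n])) < 1e-15

    def test_bolus_event_exact(self, mouse):
        model = build_model(mouse, load_compound("antibody_7e3"))
        dose = 1.33e-3
        res = simulate(model, [DoseEvent(0.0, dose)], t_end=10.0, n_points=20)
        assert res.total_drug_amount()[0] == pytest.approx(dose, rel=1e-12)

    def test_mass_balance_with_all_processes(self, mouse):
        model = build_model(mouse, load_compound("domain_antibody"))
        res = simulate(model, [DoseEvent(0.0, 1e-2)], t_end=4320.0, n_points=80)
        assert res.mass_balance_residual() < 1e-6
        assert res.cumulative_losses()["renal"][-1] > 0

    def test_states_nonnegative(self, mouse):
        model = build_model(mouse, load_compound("antibody_7e3"))
        res = simulate(model, [DoseEvent(0.0, 1e-3)], t_end=14400.0, n_points=100)
        assert np.min(res.states) >= 0.0


class TestTumorTarget:
    def test_homeostasis_without_drug(self, mouse):
        """With no drug the interstitial target stays at its baseline."""
        model = build_model(mouse, load_compound("bay_79_4620"), tumor=load_tumor_params())
        res = simulate(model, doses=[], t_end=10000.0, n_points=40)
        v_int = model.V_int[model.organ_names.index("tumor")]
        conc = res.state("target:free") / v_int
        assert np.max(np.abs(conc - 0.26)) / 0.26 < 1e-9

    def test_target_params(self):
        t = TargetBindingParams(Kd=0.004, k_on=6.0, turnover_half_life_h=38.0,
                                baseline=0.26, k_int=0.027)
        assert t.k_deg == pytest.approx(math.log(2) / (38 * 60))
        assert t.synthesis == pytest.approx(t.k_deg * 0.26)

    def test_kd_equilibrium_half_bound(self):
        """Binding-only subsystem: at C_free = Kd half the target is bound,
        i.e. the net rate vanishes when C_T == C_DT."""
        t = TargetBindingParams(Kd=0.004, k_on=6.0, turnover_half_life_h=38.0,
                                baseline=0.26, k_int=0.027)
        net = t.k_on * (t.Kd * 0.13 - t.Kd * 0.13)
        assert net == 0.0

    def test_internalization_constant_bundled(self):
        comp = load_compound("bay_79_4620")
        assert comp.target.k_int == pytest.approx(0.027)
        assert comp.target.Kd == pytest.approx(0.004)


class TestDosing:
    def test_mg_per_kg_conversion(self, mouse):
        comp = load_compound("antibody_7e3")
        # 8 mg/kg x 0.025 kg = 0.2 mg of a 150 kDa protein
        assert comp.dose_umol(8.0, mouse.body_weight) == pytest.approx(0.2 * 1000 / 150000)

    def test_invalid_dose(self):
        with pytest.raises(ValueError):
            DoseEvent(time=0.0, amount=-1.0)
        with pytest.raises(ValueError):
            DoseEvent(time=0.0, amount=1.0, duration=-5.0)


class TestReducedModelOracle:
    """Reduced whole-body model vs an independently hand-coded ODE.

    A three-compartment reduced species (pass-through lung plus two
    exchanging organs, one continuous- and one discontinuous-endothelium
    like) dosed with an inert non-catabolized solute: the package's BDF
    integration must match a hand-written right-hand side (independent
    unfactored coefficient formulas) solved by a different integrator
    (LSODA via odeint) to 1e-6 relative.
    """

    def _hand_coded_reference(self, sp, a_e, dose, t_grid):
        from proteinpbpk.constants import ETA_WATER, K_SURFACE, N_AVOGADRO, RT

        hct = sp.HCT
        organs = [sp.organs["lung"], sp.organs["liver"], sp.organs["kidney"]]
        D = RT / (6 * math.pi * N_AVOGADRO * (a_e * 1e-7) * ETA_WATER)

        def sig(g):
            if g >= 1:
                return 1.0
            return 1 - ((1 - g) ** 2 * (2 - (1 - g) ** 2) * (1 - g / 3)) / (
                1 - g / 3 + 2 / 3 * g * g)

        def xi(g):
            if g >= 1:
                return 0.0
            return (1 - g) ** 4.5 / (1 - 0.3956 * g + 1.0616 * g * g)

        A, B, Qp, L, Vp, Vi = [], [], [], [], [], []
        for o in organs:
            S = K_SURFACE * o.f_vas * o.V_org
            Lo = o.f_lymph * o.Q_blood * (1 - hct)
            Ji = o.f_Jiso * (1 - o.alpha_L) * Lo
            JL, JS = Ji + o.alpha_L * Lo, -Ji + (1 - o.alpha_L) * Lo
            gL, gS = a_e / o.r_L, a_e / o.r_S
            PSL = xi(gL) * D * (o.alpha_L * 8 * ETA_WATER * o.Lp / (o.r_L * 1e-7) ** 2) * S * 1e-3
            PSS = xi(gS) * D * ((1 - o.alpha_L) * 8 * ETA_WATER * o.Lp / (o.r_S * 1e-7) ** 2) * S * 1e-3
            conv = JL * (1 - sig(gL)) + JS * (1 - sig(gS))
            diff = 0.0
            for J, s, PS in ((JL, sig(gL), PSL), (JS, sig(gS), PSS)):
                if PS > 0:
                    pe = J * (1 - s) / PS
                    diff += PS * (pe / math.expm1(pe) if pe != 0 else 1.0)
            A.append(conv)
            B.append(diff)
            Qp.append(o.Q_blood * (1 - hct))
            L.append(Lo)
            Vp.append(o.f_vas * o.V_org * (1 - hct))
            Vi.append(o.f_int * o.V_org)
        V_art = sp.blood_pools["arterial"] * (1 - hct)
        V_ven = sp.blood_pools["venous"] * (1 - hct)
        COp = Qp[0]
        kiv = 0.96

        def rhs(y, t):
            # layout: [pls x3, int x3, art, ven]
            dy = np.zeros(8)
            C_v = [y[i] / Vp[i] for i in range(3)]
            C_i = [y[3 + i] / Vi[i] for i in range(3)]
            C_art, C_ven = y[6] / V_art, y[7] / V_ven
            inflow = [COp * C_ven, Qp[1] * C_art, Qp[2] * C_art]
            for i in range(3):
                Jvi = A[i] * C_v[i] + B[i] * (C_v[i] - C_i[i] / kiv)
                dy[i] = inflow[i] - (Qp[i] - L[i]) * C_v[i] - Jvi
                dy[3 + i] = Jvi - L[i] * C_i[i]
            dy[6] = (COp - L[0]) * C_v[0] - (Qp[1] + Qp[2]) * C_art
            dy[7] = (Qp[1] - L[1]) * C_v[1] + (Qp[2] - L[2]) * C_v[2] \
                + sum(L[i] * C_i[i] for i in range(3)) - COp * C_ven
            return dy

        y0 = np.zeros(8)
        y0[7] = dose
        return odeint(rhs, y0, t_grid, rtol=1e-11, atol=1e-15)

    def test_trajectories_match(self):
        fx = make_fixture("two_organ_oracle", seed=1)
        sp = make_reduced_species(fx.params)
        comp = CompoundProperties(
            name="probe",
            molecular_weight=50000.0,
            geometry=SoluteGeometry(a_e=fx.params["a_e_nm"]),
            fcrn=FcRnBindingParams(k_ass=0.87, Kd_acidic=999999.0),
            no_endosomal_uptake=True,
        )
        model = build_model(sp, comp)
        dose = fx.params["dose_umol"]
        t_grid = np.linspace(0.0, 720.0, 97)
        res = simulate(model, [DoseEvent(0.0, dose)], t_grid=t_grid)
        ref = self._hand_coded_reference(sp, fx.params["a_e_nm"], dose, t_grid)

        names = model.organ_names
        mapping = {
            0: names.index("lung"),
            1: names.index("liver"),
            2: names.index("kidney"),
        }
        n = model.n_organs
        for ref_col, org_idx in mapping.items():
            for block, offset in (("pls", 0), ("int", 3)):
                mine = res.states[org_idx + (0 if block == "pls" else n)]
                theirs = ref[:, ref_col + offset]
                scale = np.max(np.abs(theirs))
                assert np.max(np.abs(mine - theirs)) / scale < 1e-6, (block, ref_col)
        # blood pools
        assert np.max(np.abs(res.state("plasma:venous") - ref[:, 7])) / np.max(ref[:, 7]) < 1e-6
        assert np.max(np.abs(res.state("plasma:arterial") - ref[:, 6])) / np.max(ref[:, 6]) < 1e-6

    def test_fixture_determinism(self):
        a = make_fixture("two_organ_oracle", seed=1)
        b = make_fixture("two_organ_oracle", seed=1)
        assert a.params == b.params
        c = make_fixture("two_organ_oracle", seed=2)
        assert c.params != a.params
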