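"""Core victim model: scaling, steady state, calibration, derived fractions."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from cpipbpk import core
from cpipbpk.exceptions import (
    CalibrationError,
    DegenerateModelError,
    InvalidParameterError,
)
from cpipbpk.params import PhysiologyRef, cp1_reference


class TestScaling:
    def test_whole_liver_scaling_arithmetic(self, phys):
        # 106 uL/min/1e6 cells x 99e6 cells/g x 1650 g -> L/h
        assert core.scale_intrinsic_clearance(106.0, phys, 1.0, 1.0) == pytest.approx(
            1038.9, rel=1e-4
        )

    def test_zero_clearance_scales_to_zero(self, phys):
        assert core.scale_intrinsic_clearance(0.0, phys) == 0.0

    def test_linear_in_gamma(self, phys):
        full = core.scale_intrinsic_clearance(106.0, phys, 1.0, 1.0)
        assert core.scale_intrinsic_clearance(106.0, phys, 1.0, 0.5) == pytest.approx(
            full / 2
        )

    def test_negative_input_rejected(self, phys):
        with pytest.raises(InvalidParameterError):
            core.scale_intrinsic_clearance(-1.0, phys)


class TestNetHepaticClint:
    def test_bile_commitment_fraction(self, cp1, phys):
        # per-cell: (106 + 31 + 0.76) * 0.612 / (0.612 + 0.76)
        cls = core.whole_liver_clearances(cp1, phys)
        uptake = cls["OATP1B1"] + cls["OATP1B3"] + cls["passive"]
        net = core.net_hepatic_intrinsic_clearance(cp1, phys)
        assert net / uptake == pytest.approx(0.612 / (0.612 + 0.76), rel=1e-9)

    def test_no_backflux_limit(self, phys):
        v = replace(cp1_reference(1.0), cl_passive_per_cell=0.0)
        cls = core.whole_liver_clearances(v, phys)
        assert core.net_hepatic_intrinsic_clearance(v, phys) == pytest.approx(
            cls["OATP1B1"] + cls["OATP1B3"]
        )

    def test_large_bile_limit(self, phys):
        v = replace(cp1_reference(1.0), cl_efflux_per_cell={"MRP2": 1e9})
        cls = core.whole_liver_clearances(v, phys)
        uptake = cls["OATP1B1"] + cls["OATP1B3"] + cls["passive"]
        assert core.net_hepatic_intrinsic_clearance(v, phys) == pytest.approx(
            uptake, rel=1e-6
        )

    def test_no_hepatocyte_exit_is_degenerate(self, phys):
        v = replace(
            cp1_reference(1.0),
            cl_passive_per_cell=0.0,
            cl_efflux_per_cell={"MRP2": 0.0},
        )
        with pytest.raises(DegenerateModelError):
            core.net_hepatic_intrinsic_clearance(v, phys)


class TestRhs:
    def test_synthesis_only_from_empty_state(self, cp1, phys):
        dy = core.biomarker_rhs([0.0, 0.0, 0.0], cp1, phys)
        assert dy[0] > 0
        assert dy[1] == 0 and dy[2] == 0

    def test_steady_state_is_fixed_point(self, cp1, phys):
        ss = core.steady_state_amounts(cp1, phys)
        dy = core.biomarker_rhs(ss, cp1, phys)
        assert np.max(np.abs(dy)) < 1e-9 * np.max(np.abs(ss))

    def test_competitive_halving_at_iu_equal_ki(self, cp1, phys):
        state = core.steady_state_amounts(cp1, phys)
        dy0 = core.biomarker_rhs(state, cp1, phys)
        dy1 = core.biomarker_rhs(
            state, cp1, phys, inhibition={"OATP1B1": 1.0, "OATP1B3": 1.0}
        )
        cls = core.whole_liver_clearances(cp1, phys)
        uptake_flux = (
            (cls["OATP1B1"] + cls["OATP1B3"])
            * cp1.fu_plasma
            * state[1]
            / phys.v_liver_extracellular
        )
        # the uptake flux into hepatocytes is exactly halved
        assert dy1[2] - dy0[2] == pytest.approx(-uptake_flux / 2, rel=1e-9)

    def test_negative_state_rejected(self, cp1, phys):
        with pytest.raises(InvalidParameterError):
            core.biomarker_rhs([-1.0, 0.0, 0.0], cp1, phys)


class TestBaseline:
    def test_reference_baseline_concentration(self, cp1, phys):
        # synthesis 70 kg x 0.0036 mg/day/kg = 384.9 nmol/day; CL 23 L/h
        res = core.solve_baseline(cp1, phys)
        assert res.css_plasma == pytest.approx(0.697, rel=2e-3)
        assert res.cl_total_plasma == pytest.approx(23.0, rel=1e-6)

    def test_css_linear_in_synthesis(self, cp1, phys):
        res1 = core.solve_baseline(cp1, phys)
        res2 = core.solve_baseline(replace(cp1, k_syn=2 * cp1.k_syn), phys)
        assert res2.css_plasma == pytest.approx(2 * res1.css_plasma, rel=1e-9)

    def test_removing_renal_pathway(self, cp1, phys):
        res0 = core.solve_baseline(cp1, phys)
        res = core.solve_baseline(replace(cp1, cl_renal_plasma=0.0), phys)
        assert res.css_plasma > res0.css_plasma
        assert res.fe == 0.0

    def test_requires_synthesis(self, cp1, phys):
        with pytest.raises(InvalidParameterError):
            core.solve_baseline(replace(cp1, k_syn=0.0), phys)

    def test_ode_trajectory_reaches_linear_steady_state(self, cp1, phys):
        ss = core.steady_state_amounts(cp1, phys)
        states = core.simulate_victim(
            cp1, phys, np.linspace(0.0, 2000.0, 21), y0=np.zeros(3)
        )
        assert np.max(np.abs(states[-1] - ss) / ss) < 1e-4

    def test_mass_balance_over_interval(self, cp1, phys):
        t = np.linspace(0.0, 24.0, 241)
        states = core.simulate_victim(cp1, phys, t, y0=np.zeros(3))
        r_syn = cp1.synthesis_rate_nmol_h(phys.body_weight)
        cls = core.whole_liver_clearances(cp1, phys)
        renal = cp1.cl_renal_plasma * states[:, 0] / phys.v_central_plasma
        bile = cls["bile"] * states[:, 2] / phys.v_liver_intracellular
        out = np.trapezoid(renal + bile, t)
        synth_in = r_syn * t[-1]
        assert abs(synth_in - out - states[-1].sum()) < 1e-3 * synth_in


class TestCalibration:
    def test_gamma_matches_well_stirred_inversion(self, cp1, phys):
        # closed-form oracle: CLh,p = 0.9 x 23 = 20.7 L/h at fe = 0.10
        oracle = core.well_stirred_gamma(cp1_reference(), phys, 20.7)
        assert cp1.hepatic_scaler_gamma == pytest.approx(oracle, rel=1e-2)
        assert cp1.hepatic_scaler_gamma == pytest.approx(0.80, abs=0.01)

    def test_identity_when_target_is_own_css(self, phys):
        v = cp1_reference(1.0)
        css = core.solve_baseline(v, phys).css_plasma
        gamma = core.calibrate_hepatic_scaler(v, phys, {"css": css})
        assert gamma == pytest.approx(1.0, rel=1e-6)

    def test_unattainable_fe_raises_with_bracket(self, phys):
        with pytest.raises(CalibrationError, match="unattainable"):
            # renal-only floor: fe cannot fall below CL_R/(CL_R + flow limit)
            core.calibrate_hepatic_scaler(cp1_reference(), phys, {"fe": 0.01})
        with pytest.raises(CalibrationError):
            core.calibrate_hepatic_scaler(cp1_reference(), phys, {"fe": 1.0})

    def test_calibrated_target_reached(self, cp1_css, phys):
        assert core.solve_baseline(cp1_css, phys).css_plasma == pytest.approx(
            0.685, rel=1e-3
        )


class TestDerivedFractions:
    def test_fe_at_literature_baseline(self, cp1_css, phys):
        res = core.solve_baseline(cp1_css, phys)
        assert 0.095 <= core.compute_fe(res) <= 0.101
        assert core.compute_fe(res) == pytest.approx(res.fe, abs=1e-6)

    def test_fe_edge_cases(self, cp1, phys):
        assert core.solve_baseline(replace(cp1, cl_renal_plasma=0.0), phys).fe == 0.0

    def test_ft_at_fe_10pct(self, cp1):
        ft = core.compute_ft(cp1, 0.10)
        assert ft["OATP1B1"] == pytest.approx(0.693, abs=0.001)
        assert ft["OATP1B3"] == pytest.approx(0.203, abs=0.001)
        assert sum(ft.values()) == pytest.approx(1.0, abs=1e-12)

    def test_ft_at_fe_zero(self, cp1):
        assert core.compute_ft(cp1, 0.0)["OATP1B1"] == pytest.approx(0.769, abs=0.001)

    def test_ft_single_pathway_splits_evenly(self, phys):
        v = replace(
            cp1_reference(1.0),
            cl_uptake_per_cell={"OATP1B1": 50.0},
            cl_passive_per_cell=0.0,
            raf={"OATP1B1": 1.0, "MRP2": 1.0},
        )
        assert core.compute_ft(v, 0.5)["OATP1B1"] == pytest.approx(0.5)

    def test_passive_uptake_share(self, cp1):
        # 0.76 / (0.76 + 137)
        share = core.fraction_passive_uptake(cp1)
        assert share == pytest.approx(0.0055, abs=2e-4)
        assert share < 0.01

    def test_passive_share_edges(self, phys):
        v = replace(cp1_reference(1.0), cl_passive_per_cell=0.0)
        assert core.fraction_passive_uptake(v) == 0.0
        v = replace(cp1_reference(1.0), cl_passive_per_cell=137.0)
        assert core.fraction_passive_uptake(v) == pytest.approx(0.5, abs=1e-9)


class TestInvariantProperties:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.25, 4.0),
        ksyn=st.floats(0.001, 0.01),
    )
    def test_homogeneity_of_baseline(self, phys, scale, ksyn):
        """css is linear in k_syn and inverse-linear in a uniform clearance
        scaling."""
        v = replace(cp1_reference(1.0), k_syn=ksyn)
        ref = core.solve_baseline(v, phys).css_plasma
        scaled = replace(
            v,
            cl_renal_plasma=v.cl_renal_plasma * scale,
            cl_passive_per_cell=v.cl_passive_per_cell * scale,
            cl_uptake_per_cell={t: c * scale for t, c in v.cl_uptake_per_cell.items()},
            cl_efflux_per_cell={t: c * scale for t, c in v.cl_efflux_per_cell.items()},
        )
        # flows must scale too for exact inverse-linearity
        phys2 = replace(
            phys,
            q_hepatic_blood=phys.q_hepatic_blood * scale,
            q_portal_blood=phys.q_portal_blood * scale,
        )
        assert core.solve_baseline(scaled, phys2).css_plasma == pytest.approx(
            ref / scale, rel=1e-9
        )

    @pytest.mark.parametrize(
        "field,factor",
        [
            ("cl_renal_plasma", 1.5),
            ("cl_uptake_per_cell", 1.5),
            ("cl_efflux_per_cell", 1.5),
        ],
    )
    def test_css_decreases_when_any_clearance_increases(self, cp1, phys, field, factor):
        ref = core.solve_baseline(cp1, phys).css_plasma
        value = getattr(cp1, field)
        bumped = (
            {t: c * factor for t, c in value.items()}
            if isinstance(value, dict)
            else value * factor
        )
        res = core.solve_baseline(replace(cp1, **{field: bumped}), phys)
        assert res.css_plasma < ref

    def test_passive_backflux_raises_baseline(self, cp1, phys):
        """Passive diffusion is a futile cycle here: with biliary efflux far
        below uptake, raising CLpd increases backflux more than influx, so
        net hepatic clearance falls and the baseline rises."""
        ref = core.solve_baseline(cp1, phys).css_plasma
        res = core.solve_baseline(replace(cp1, cl_passive_per_cell=7.6), phys)
        assert res.css_plasma > ref

    def test_fe_plus_hepatic_fractions_is_one(self, cp1, phys):
        res = core.solve_baseline(cp1, phys)
        assert sum(res.ft.values()) == pytest.approx(1.0, abs=1e-9)
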