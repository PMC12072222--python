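"""DDI engine: metrics, control/treatment coupling, static oracles."""

import numpy as np
import pytest
from dataclasses import replace

from cpipbpk import core, ddi
from cpipbpk.exceptions import (
    AmbiguousVictimError,
    CalibrationError,
    InvalidParameterError,
)
from cpipbpk.ki import generic_statin_victim
from cpipbpk.params import DosingRegimen, cp1_reference


class TestInhibitedClint:
    def test_competitive_scaling(self):
        assert ddi.inhibited_clint(100.0, 0.0, 1.0) == 100.0
        assert ddi.inhibited_clint(100.0, 1.0, 1.0) == 50.0
        assert ddi.inhibited_clint(100.0, 9.0, 1.0) == pytest.approx(10.0)

    def test_invalid_ki(self):
        with pytest.raises(InvalidParameterError):
            ddi.inhibited_clint(100.0, 1.0, 0.0)


class TestExposureMetrics:
    def test_constant_profile(self):
        t = np.linspace(0, 24, 241)
        cmax, tmax, auc = ddi.exposure_metrics(t, np.full(241, 2.0), (0, 24))
        assert (cmax, tmax) == (2.0, 0.0)
        assert auc == pytest.approx(48.0)

    def test_linear_ramp_auc(self):
        t = np.linspace(0, 1, 101)
        _, _, auc = ddi.exposure_metrics(t, t, (0, 1))
        assert auc == pytest.approx(0.5, abs=1e-9)

    def test_exponential_decay_auc(self):
        t = np.linspace(0, 20, 2001)
        _, _, auc = ddi.exposure_metrics(t, np.exp(-t), (0, 20))
        assert auc == pytest.approx(1.0, abs=1e-4)

    def test_window_not_covered(self):
        with pytest.raises(InvalidParameterError):
            ddi.exposure_metrics([0, 1], [1, 1], (5, 6))


class TestSimulateDDI:
    def test_null_interaction_with_huge_ki(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        weak = inh.with_ki({t: 1e9 for t in inh.ki})
        out = ddi.simulate_ddi(cp1, weak, reg, phys, (0, 24))
        assert out.cmax_ratio == pytest.approx(1.0, abs=5e-3)
        assert out.auc_ratio == pytest.approx(1.0, abs=5e-3)

    def test_zero_dose_reproduces_control(self, cp1, phys, rifampicin_like):
        inh, _ = rifampicin_like
        out = ddi.simulate_ddi(cp1, inh, DosingRegimen(dose=0.0), phys, (0, 24))
        assert np.allclose(out.conc_treatment, out.conc_control, rtol=1e-9)

    def test_control_cmax_is_baseline(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        out = ddi.simulate_ddi(cp1, inh, reg, phys, (0, 24))
        css = core.solve_baseline(cp1, phys).css_plasma
        assert out.control_metrics[0] == pytest.approx(css, rel=1e-9)

    def test_ratios_exceed_one_for_pure_inhibition(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        out = ddi.simulate_ddi(cp1, inh, reg, phys, (0, 24))
        assert out.cmax_ratio > 1.0
        assert out.auc_ratio > 1.0
        assert out.cmax_ratio >= out.auc_ratio

    def test_dose_response_is_monotone(self, cp1, phys, rifampicin_like):
        inh, _ = rifampicin_like
        metrics = []
        for dose in (150.0, 300.0, 600.0):
            out = ddi.simulate_ddi(
                cp1, inh, DosingRegimen(dose=dose), phys, (0, 24),
                keep_profiles=False,
            )
            metrics.append((out.cmax_ratio, out.auc_ratio))
        assert metrics == sorted(metrics)

    def test_uncalibrated_victim_rejected(self, phys, rifampicin_like):
        inh, reg = rifampicin_like
        with pytest.raises(CalibrationError):
            ddi.simulate_ddi(cp1_reference(), inh, reg, phys, (0, 24))

    def test_ambiguous_victim_rejected(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        with pytest.raises(AmbiguousVictimError):
            ddi.simulate_ddi(
                cp1, inh, reg, phys, (0, 24),
                victim_regimen=DosingRegimen(dose=10.0),
            )


class TestStaticOracles:
    def test_dynamic_converges_to_static_at_constant_exposure(self, cp1, phys):
        """Holding Iu/Ki constant, the long-run dynamic concentration ratio
        equals the well-stirred clearance ratio (within 2 %)."""
        const = {"OATP1B1": 1.0, "OATP1B3": 1.0}
        want = ddi.static_ratio(cp1, phys, const)
        y0 = core.steady_state_amounts(cp1, phys)
        states = core.simulate_victim(
            cp1, phys, np.linspace(0, 200, 201), y0=y0,
            inhibition_fn=lambda t: const,
        )
        got = states[-1, 0] / y0[0]
        assert got == pytest.approx(want, rel=0.02)

    def test_uptake_limited_formula_reference_value(self, cp1):
        # classical static formula on pathway fractions at Iu = Ki
        ft = core.compute_ft(cp1, 0.10)
        val = ddi.static_aucr_uptake_limited(ft, {"OATP1B1": 1.0, "OATP1B3": 1.0})
        assert val == pytest.approx(1.82, abs=0.01)

    def test_flow_limitation_damps_below_uptake_limited(self, cp1, phys):
        ft = core.compute_ft(cp1, 0.10)
        const = {"OATP1B1": 1.0, "OATP1B3": 1.0}
        assert ddi.static_ratio(cp1, phys, const) < ddi.static_aucr_uptake_limited(
            ft, const
        )

    def test_aucr_ceiling_bounds_strong_inhibition(self, cp1, phys):
        ceiling = ddi.aucr_ceiling(cp1, phys)
        near = ddi.static_ratio(cp1, phys, {"OATP1B1": 1e6, "OATP1B3": 1e6})
        assert near <= ceiling + 1e-9
        assert near == pytest.approx(ceiling, rel=1e-3)
        # the pathway-fraction bound 1/(fe + ft_passive) lies above it
        ft = core.compute_ft(cp1, 0.10)
        assert ceiling <= 1.0 / (ft["renal"] + ft["passive"]) + 1e-9


class TestDosedVictim:
    def test_no_inhibitor_gives_unit_ratio(self, phys, rifampicin_like):
        statin = generic_statin_victim(phys)
        inh, _ = rifampicin_like
        out = ddi.simulate_ddi(
            statin, inh, DosingRegimen(dose=0.0), phys, (0, 24),
            victim_regimen=DosingRegimen(dose=10.0),
        )
        assert out.auc_ratio == pytest.approx(1.0, abs=1e-9)

    def test_stronger_inhibitor_gives_larger_aucr(self, phys, rifampicin_like):
        statin = generic_statin_victim(phys)
        inh, reg = rifampicin_like
        vreg = DosingRegimen(dose=10.0)
        weak = ddi.simulate_ddi(
            statin, inh.with_ki({t: 10 * k for t, k in inh.ki.items()}),
            reg, phys, (0, 24), victim_regimen=vreg, keep_profiles=False,
        )
        strong = ddi.simulate_ddi(
            statin, inh, reg, phys, (0, 24), victim_regimen=vreg,
            keep_profiles=False,
        )
        assert strong.auc_ratio > weak.auc_ratio > 1.0

    def test_renal_only_victim_untouched_by_oatp1b_inhibition(
        self, phys, rifampicin_like
    ):
        statin = generic_statin_victim(phys)
        renal_only = replace(
            statin,
            cl_uptake_per_cell={t: 0.0 for t in statin.cl_uptake_per_cell},
            cl_passive_per_cell=0.0,
        ).with_gamma(1.0)
        inh, reg = rifampicin_like
        out = ddi.simulate_ddi(
            renal_only, inh, reg, phys, (0, 24),
            victim_regimen=DosingRegimen(dose=10.0),
        )
        assert out.auc_ratio == pytest.approx(1.0, abs=1e-6)
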