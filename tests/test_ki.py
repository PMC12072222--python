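"""In vivo Ki estimation, clearance repartition and fe sensitivity."""

import numpy as np
import pytest

from cpipbpk import core, ddi, ki
from cpipbpk.exceptions import InfeasibleObservationError, InvalidParameterError
from cpipbpk.params import DosingRegimen
from cpipbpk.synthetic import generate_ddi_dataset


class TestRatioEstimator:
    @pytest.mark.parametrize("true_ki", [0.02, 0.16, 1.0])
    def test_forward_inverse_round_trip(self, cp1, phys, rifampicin_like, true_ki):
        inh, reg = rifampicin_like
        truth = inh.with_ki(
            {t: k * true_ki / inh.ki["OATP1B1"] for t, k in inh.ki.items()}
        )
        out = ddi.simulate_ddi(cp1, truth, reg, phys, (0, 24), keep_profiles=False)
        est = ki.estimate_ki_from_ratio(
            out.auc_ratio, "AUCR", cp1, inh, reg, phys
        )
        assert est.ki_in_vivo == pytest.approx(true_ki, rel=0.01)
        # isoform ratio preserved at the in vitro value
        assert est.ki_map["OATP1B3"] / est.ki_map["OATP1B1"] == pytest.approx(
            inh.ki["OATP1B3"] / inh.ki["OATP1B1"]
        )

    def test_cmaxr_objective_round_trip(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        out = ddi.simulate_ddi(cp1, inh, reg, phys, (0, 24), keep_profiles=False)
        est = ki.estimate_ki_from_ratio(out.cmax_ratio, "CmaxR", cp1, inh, reg, phys)
        assert est.ki_in_vivo == pytest.approx(inh.ki["OATP1B1"], rel=0.01)
        assert est.objective == "cmaxr_match"

    def test_ratio_above_ceiling_is_infeasible(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        ceiling = ddi.aucr_ceiling(cp1, phys)
        with pytest.raises(InfeasibleObservationError) as err:
            ki.estimate_ki_from_ratio(ceiling + 1.0, "AUCR", cp1, inh, reg, phys)
        assert err.value.ceiling == pytest.approx(ceiling)

    def test_small_elevation_gives_finite_ki(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        est = ki.estimate_ki_from_ratio(1.05, "AUCR", cp1, inh, reg, phys)
        assert np.isfinite(est.ki_in_vivo) and est.ki_in_vivo > 0

    def test_invalid_observed_ratio(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        with pytest.raises(InvalidParameterError):
            ki.estimate_ki_from_ratio(0.9, "AUCR", cp1, inh, reg, phys)


class TestRepartition:
    def test_identity_at_current_fe(self, cp1, phys):
        v = ki.repartition_clearance(cp1, phys, 0.10)
        b0 = core.solve_baseline(cp1, phys)
        b1 = core.solve_baseline(v, phys)
        assert b1.css_plasma == pytest.approx(b0.css_plasma, rel=1e-3)
        assert v.cl_renal_plasma == pytest.approx(cp1.cl_renal_plasma, rel=1e-3)

    @pytest.mark.parametrize("fe_new", [0.0, 0.05, 0.15])
    def test_css_conserved_across_repartition(self, cp1, phys, fe_new):
        v = ki.repartition_clearance(cp1, phys, fe_new)
        b0 = core.solve_baseline(cp1, phys)
        b1 = core.solve_baseline(v, phys)
        assert b1.css_plasma == pytest.approx(b0.css_plasma, rel=1e-3)
        assert b1.fe == pytest.approx(fe_new, abs=1e-6)

    def test_ft_shift_with_fe(self, cp1, phys):
        v = ki.repartition_clearance(cp1, phys, 0.15)
        assert core.compute_ft(v, 0.15)["OATP1B1"] == pytest.approx(0.654, abs=0.001)

    def test_invalid_fe(self, cp1, phys):
        with pytest.raises(InvalidParameterError):
            ki.repartition_clearance(cp1, phys, 1.0)


class TestFeSensitivity:
    def test_ki_strictly_decreasing_in_fe(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        tab = ki.fe_sensitivity(
            3.0, "AUCR", cp1, inh, reg, phys, [0.0, 0.10, 0.15]
        )
        assert (np.diff(tab.ki_uM) < 0).all()
        assert (tab.downstream_aucr > 1).all()

    def test_ki_decreasing_in_observed_ratio(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        k_lo = ki.estimate_ki_from_ratio(1.5, "AUCR", cp1, inh, reg, phys)
        k_hi = ki.estimate_ki_from_ratio(3.5, "AUCR", cp1, inh, reg, phys)
        assert k_hi.ki_in_vivo < k_lo.ki_in_vivo


class TestProfileEstimator:
    def test_noise_free_recovery(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        times = list(np.array([0, 1, 2, 4, 6, 8, 12, 24], dtype=float))
        df, truth = generate_ddi_dataset(
            cp1, inh, reg, phys, true_ki_scale=0.5, sampling_times=times,
            cv_residual=0.0, n_subjects=1, seed=0,
        )
        obs = (
            df[df.arm == "treatment"].sort_values("time_h").conc_nM.to_numpy()
        )
        est = ki.estimate_ki_from_profile(times, obs, cp1, inh, reg, phys)
        assert est.ki_in_vivo == pytest.approx(0.5 * inh.ki["OATP1B1"], rel=0.02)
        assert est.convergence["non_identifiable"] == 0.0

    def test_zero_dose_flags_non_identifiable(self, cp1, phys, rifampicin_like):
        inh, _ = rifampicin_like
        times = [0.0, 4.0, 8.0, 24.0]
        css = core.solve_baseline(cp1, phys).css_plasma
        with pytest.warns(UserWarning, match="identifiable"):
            est = ki.estimate_ki_from_profile(
                times, [css] * 4, cp1, inh, DosingRegimen(dose=0.0), phys
            )
        assert est.convergence["non_identifiable"] == 1.0

    def test_too_few_observations_rejected(self, cp1, phys, rifampicin_like):
        inh, reg = rifampicin_like
        with pytest.raises(InvalidParameterError):
            ki.estimate_ki_from_profile([0.0, 24.0], [0.7, 0.9], cp1, inh, reg, phys)


class TestGenericStatin:
    def test_design_targets(self, phys):
        statin = ki.generic_statin_victim(phys)
        ft = core.compute_ft(statin, 0.10)
        assert ft["OATP1B1"] + ft["OATP1B3"] == pytest.approx(0.70, abs=0.01)
        # fe target reached for the dosed compound (checked via clearances)
        cl_h = core.hepatic_plasma_clearance(statin, phys)
        fe = statin.cl_renal_plasma / (statin.cl_renal_plasma + cl_h)
        assert fe == pytest.approx(0.10, abs=1e-3)
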