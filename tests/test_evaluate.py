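import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import KaplanMeierFitter

from asjm import (
    UndefinedMetricError,
    calibration_curve,
    default_cohort_params,
    default_protocol,
    diagnostic_accuracy,
    net_biopsies_avoided,
    point_fit,
    recalibrate,
    reconstruct_confusion_from_deferral,
    simulate_cohort,
    time_dependent_auc,
)
from asjm.evaluate import ConfusionPer1000, round_half_away
from asjm._core import cumulative_hazard_linear, linpred_coefs


def brute_force_auc(risks, cases, ctrls):
    num = den = 0.0
    for i in np.flatnonzero(cases):
        for j in np.flatnonzero(ctrls):
            num += (risks[i] > risks[j]) + 0.5 * (risks[i] == risks[j])
            den += 1
    return num / den


class TestTimeDependentAUC:
    def test_perfect_ranking_is_one(self):
        times = np.array([2.0, 2.5, 9.0, 9.0, 9.0])
        events = np.array([True, True, False, False, False])
        risks = np.array([0.9, 0.8, 0.1, 0.2, 0.3])
        assert time_dependent_auc(risks, times, events, 1.5, 2.5) == 1.0

    def test_all_ties_is_half(self):
        times = np.array([2.0, 2.5, 9.0, 9.0])
        events = np.array([True, True, False, False])
        risks = np.full(4, 0.2)
        assert time_dependent_auc(risks, times, events, 1.5, 2.5) == 0.5

    def test_matches_exhaustive_pairwise_oracle_exactly(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            n = rng.integers(10, 50)
            times = rng.uniform(0.5, 8.0, n)
            events = rng.random(n) < 0.5
            # uncensored design: everyone's status at the window end is known
            times[~events] = 9.0
            risks = np.round(rng.random(n), 2)  # ties likely
            landmark, window = 0.4, 4.0
            at = times > landmark
            cases = at & events & (times <= landmark + window)
            ctrls = at & (times > landmark + window)
            if cases.sum() == 0 or ctrls.sum() == 0:
                continue
            expected = brute_force_auc(risks, cases, ctrls)
            assert time_dependent_auc(risks, times, events, landmark, window) == expected

    def test_undefined_without_cases_or_controls(self):
        times = np.array([9.0, 9.0])
        events = np.array([False, False])
        with pytest.raises(UndefinedMetricError):
            time_dependent_auc(np.array([0.1, 0.2]), times, events, 1.0, 2.0)

    def test_ipcw_variant_close_to_restricted_on_light_censoring(self):
        rng = np.random.default_rng(3)
        n = 400
        times = rng.uniform(0.5, 10.0, n)
        events = rng.random(n) < 0.4
        risks = np.clip(0.5 * events + rng.normal(0, 0.25, n), 0, 1)
        a = time_dependent_auc(risks, times, events, 1.0, 2.0)
        b = time_dependent_auc(risks, times, events, 1.0, 2.0, ipcw=True)
        assert abs(a - b) < 0.05


class TestConfusionPer1000:
    @given(
        st.integers(5, 400),
        st.floats(0.01, 0.99),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=40, deadline=None)
    def test_identities_hold_for_generated_rows(self, n, thr, seed):
        rng = np.random.default_rng(seed)
        risks = rng.random(n)
        outcomes = rng.random(n) < 0.3
        if outcomes.sum() == 0 or outcomes.sum() == n:
            return
        for conf in diagnostic_accuracy(risks, outcomes, [thr]):
            assert conf.tp + conf.fp + conf.tn + conf.fn == pytest.approx(1000, abs=1e-9)
            if conf.tp + conf.fn > 0:
                assert conf.sens == pytest.approx(
                    100 * conf.tp / (conf.tp + conf.fn), abs=1e-9
                )
            if conf.tn + conf.fn > 0:
                assert conf.npv == pytest.approx(
                    100 * conf.tn / (conf.tn + conf.fn), abs=1e-9
                )
            assert conf.biopsies_delayed == conf.tn + conf.fn
            assert conf.reclassifications_delayed == conf.fn

    def test_zero_threshold_biopsies_everyone(self):
        risks = np.array([0.0, 0.2, 0.9])
        outcomes = np.array([False, True, True])
        conf = diagnostic_accuracy(risks, outcomes, [0.0])[0]
        assert conf.sens == 100.0
        assert conf.biopsies_delayed == 0.0

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_accuracy(np.array([0.1]), np.array([True]), [])

    def test_wilson_intervals_bracket_the_estimate(self):
        rng = np.random.default_rng(5)
        risks = rng.random(300)
        outcomes = rng.random(300) < 0.3
        conf = diagnostic_accuracy(risks, outcomes, [0.3])[0]
        for which in ("sens", "spec", "npv", "ppv"):
            lo, hi = conf.wilson_ci(which)
            assert lo <= getattr(conf, which) <= hi


class TestReconstructFromDeferral:
    def test_registry_year15_threshold75_row(self):
        """Printed columns sens 92, 354 deferred, 11 delayed imply prevalence
        137.5/1000, tp 126.5, specificity ~40 and NPV 97."""
        conf = reconstruct_confusion_from_deferral(92, 354, 11)
        assert conf.prevalence_per_1000 == pytest.approx(137.5)
        assert conf.tp == pytest.approx(126.5)
        assert round_half_away(conf.spec) == 40
        assert round_half_away(conf.npv) == 97

    def test_threshold10_row(self):
        conf = reconstruct_confusion_from_deferral(84, 480, 24)
        assert conf.prevalence_per_1000 == pytest.approx(150.0)
        assert conf.tp == pytest.approx(126.0)
        assert conf.fp == pytest.approx(394.0)

    def test_perfect_sensitivity_forces_perfect_npv(self):
        conf = reconstruct_confusion_from_deferral(100, 300, 0)
        assert conf.npv == 100.0

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion_from_deferral(100, 300, 5)
        with pytest.raises(ValueError):
            reconstruct_confusion_from_deferral(90, 10, 20)


class TestNetBenefit:
    def test_biopsy_all_policy_avoids_nothing(self):
        conf = ConfusionPer1000(threshold=0.0, tp=150.0, fp=850.0, tn=0.0, fn=0.0)
        nb = net_biopsies_avoided(conf, 0.1)
        assert nb.net_biopsies_avoided_per_100 == pytest.approx(0.0, abs=1e-12)
        assert nb.nb_none == 0.0

    def test_threshold_equal_to_prevalence_reduces(self):
        conf = ConfusionPer1000(threshold=0.15, tp=100.0, fp=300.0, tn=550.0, fn=50.0)
        pt = conf.prevalence_per_1000 / 1000.0
        nb = net_biopsies_avoided(conf, pt)
        assert nb.nb_all == pytest.approx(0.0, abs=1e-12)
        assert nb.net_biopsies_avoided_per_100 == pytest.approx(
            100 * nb.nb_model * (1 - pt) / pt
        )

    def test_hand_computed_toy_table(self):
        conf = ConfusionPer1000(threshold=0.2, tp=120.0, fp=280.0, tn=540.0, fn=60.0)
        pt = 0.2
        nb = net_biopsies_avoided(conf, pt)
        # spreadsheet-style steps
        ex = pt / (1 - pt)
        nb_model = 0.120 - 0.280 * ex
        nb_all = 0.180 - 0.820 * ex
        assert nb.nb_model == pytest.approx(nb_model, abs=1e-12)
        assert nb.nb_all == pytest.approx(nb_all, abs=1e-12)
        assert nb.net_biopsies_avoided_per_100 == pytest.approx(
            100 * (nb_model - nb_all) / ex, abs=1e-12
        )


class TestCalibration:
    def test_constant_risk_gives_single_matching_point(self):
        n = 200
        risks = np.full(n, 0.3)
        events = np.zeros(n, dtype=bool)
        events[:60] = True
        times = np.where(events, 1.0, 10.0)
        frame, overall = calibration_curve(risks, times, events, horizon=5.0, n_bins=10)
        assert len(frame) == 1
        assert frame["mean_predicted"].iloc[0] == pytest.approx(0.3)
        assert frame["observed"].iloc[0] == pytest.approx(0.3)
        assert overall == (pytest.approx(0.3), pytest.approx(0.3))

    def _latent_world(self, n, hazard_scale, seed):
        p = default_cohort_params(n)
        records, truth = simulate_cohort(p, default_protocol(), seed=seed)
        b = np.asarray(truth["ranefs"])
        age = np.array([r.age_at_diagnosis for r in records])
        a, c = linpred_coefs(p.model, b, age)
        risks = 1 - np.exp(-cumulative_hazard_linear(p.model, a, c, 5.0))
        lat = np.array([np.inf if t is None else t for t in truth["latent_event_times"]])
        events = lat <= 5.0
        times = np.minimum(lat, 5.0 + 1e-6)
        return risks / 1.0, times, events  # hazard_scale applied by caller's params

    def test_self_consistent_generator_slope_near_one(self):
        """Risks computed from the generating model against its own latent
        outcomes: observed-vs-predicted slope close to 1."""
        risks, times, events = self._latent_world(2000, 1.0, seed=60)
        frame, _ = calibration_curve(risks, times, events, horizon=5.0, n_bins=10)
        x = frame["mean_predicted"].to_numpy()
        y = frame["observed"].to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert abs(slope - 1.0) < 0.1

    def test_doubled_hazard_underpredicts_in_every_bin(self):
        p = default_cohort_params(2000)
        p.model.h0[:] *= 2.0
        records, truth = simulate_cohort(p, default_protocol(), seed=61)
        single = default_cohort_params(10).model  # original hazard for predictions
        b = np.asarray(truth["ranefs"])
        age = np.array([r.age_at_diagnosis for r in records])
        a, c = linpred_coefs(single, b, age)
        risks = 1 - np.exp(-cumulative_hazard_linear(single, a, c, 5.0))
        lat = np.array([np.inf if t is None else t for t in truth["latent_event_times"]])
        events = lat <= 5.0
        times = np.minimum(lat, 5.0 + 1e-6)
        frame, _ = calibration_curve(risks, times, events, horizon=5.0, n_bins=8)
        assert (frame["observed"] > frame["mean_predicted"]).all()


class TestRecalibrate:
    """Hazard-scale transport checks on the dense-biopsy protocol, where
    detection closely tracks the latent event time."""

    def test_training_cohort_is_near_fixed_point(self):
        from asjm.cohort_sim import recovery_cohort_params, recovery_protocol

        base = recovery_cohort_params(1000)
        records, _ = simulate_cohort(base, recovery_protocol(), seed=62)
        updated = recalibrate(point_fit(base.model), records)
        assert abs(updated.recalibration_log_shift) < 0.15

    def test_doubled_hazard_recovers_log_two(self):
        from asjm.cohort_sim import recovery_cohort_params, recovery_protocol

        base = recovery_cohort_params(1000)
        train, _ = simulate_cohort(base, recovery_protocol(), seed=62)
        fit0 = recalibrate(point_fit(base.model), train)
        doubled = recovery_cohort_params(1000)
        doubled.model.h0[:] *= 2.0
        records, _ = simulate_cohort(doubled, recovery_protocol(), seed=63)
        updated = recalibrate(fit0, records)
        assert updated.recalibration_log_shift == pytest.approx(np.log(2.0), abs=0.15)

    def test_no_events_rejected(self, truth_fit):
        from asjm import PatientRecord

        recs = [PatientRecord(f"P{i}", 65.0, [(0.0, "psa", 6.0)], censor_time_y=5.0)
                for i in range(5)]
        with pytest.raises(ValueError, match="no events"):
            recalibrate(truth_fit, recs)
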