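import numpy as np
import pytest

from asjm import (
    ModelParams,
    PatientRecord,
    SubmodelSpec,
    TimeBasis,
    instantaneous_velocity,
    point_fit,
    posterior_profile,
)
from asjm.longitudinal import PatientState, build_design
from asjm._core import ParamDraws


def make_record(pid="A", age=65.0, psa=(), volume=(), biopsies=(), mri=(),
                censor=10.0):
    obs = []
    obs += [(t, "psa", v) for t, v in psa]
    obs += [(t, "volume", v) for t, v in volume]
    obs += [(t, "mri_lesion", v) for t, v in mri]
    obs += [(t, "biopsy_gg", v) for t, v in biopsies]
    obs.sort()
    return PatientRecord(pid, age, obs, censor_time_y=censor)


class TestBuildDesign:
    @pytest.mark.parametrize(
        "channel,value,expected",
        [
            ("psa", 8.0, 3.0),
            ("psa", 5.7, np.log2(5.7)),  # ~2.511, the registry's median PSA
            ("volume", 46.0, np.log2(46.0)),  # ~5.524, the registry's median volume
        ],
    )
    def test_log2_transform(self, channel, value, expected):
        rec = make_record(psa=[(0.0, value)]) if channel == "psa" else make_record(
            volume=[(0.0, value)]
        )
        d = build_design([rec], SubmodelSpec(channel))
        assert d.y[0] == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_value_names_patient_and_time(self):
        rec = PatientRecord("BAD", 65.0, [(1.5, "psa", 0.0)], censor_time_y=4.0)
        with pytest.raises(ValueError, match="BAD.*1.5"):
            build_design([rec], SubmodelSpec("psa"))

    def test_row_count_matches_observations(self, small_cohort):
        records, _ = small_cohort
        for ch in ("psa", "volume", "mri_lesion"):
            d = build_design(records, SubmodelSpec(ch))
            n_obs = sum(1 for r in records for _, c, _ in r.observations if c == ch)
            assert d.y.size == d.X.shape[0] == n_obs

    def test_benign_channel_derived_from_biopsies(self):
        rec = make_record(biopsies=[(1.0, 0.0), (4.0, 1.0), (7.0, 2.0)], censor=None)
        rec.event_time_y = 7.0
        d = build_design([rec], SubmodelSpec("benign"))
        # reclassifying biopsy excluded; benign = no cancer found
        assert d.t.tolist() == [1.0, 4.0]
        assert d.y.tolist() == [1.0, 0.0]


def gls_blup_oracle(params, t, y):
    """Closed-form posterior mean/cov of the random effects given one
    Gaussian channel: standard mixed-model matrix algebra."""
    Z = np.zeros((t.size, 6))
    Z[:, 0] = 1.0
    Z[:, 1] = t
    resid = y - (params.beta["psa"][0] + params.beta["psa"][1] * t)
    S = params.ranef_cov
    V = Z @ S @ Z.T + params.sigma["psa"] ** 2 * np.eye(t.size)
    K = S @ Z.T @ np.linalg.inv(V)
    mean = K @ resid
    cov = S - K @ Z @ S
    return mean, cov


class TestPosteriorProfile:
    def test_blup_matches_gls_oracle(self, truth_params):
        fit = point_fit(truth_params)
        t = np.array([0.0, 0.5, 1.0, 1.8, 2.5])
        y = np.array([6.0, 6.4, 5.9, 7.2, 7.5])
        rec = make_record(psa=list(zip(t, y)))
        st = posterior_profile(fit, rec, 3.0, condition_on_survival=False,
                               mode="laplace", seed=0)
        mean, cov = gls_blup_oracle(truth_params, t, np.log2(y))
        np.testing.assert_allclose(st.ranef_mean, mean, atol=1e-6)
        np.testing.assert_allclose(st.ranef_cov, cov, atol=1e-6)

    def test_no_data_shrinks_to_population(self, truth_fit, truth_params):
        rec = make_record()
        st = posterior_profile(truth_fit, rec, 1.0, condition_on_survival=False,
                               mode="laplace", seed=0)
        np.testing.assert_allclose(st.ranef_mean, 0.0, atol=1e-12)
        ts = np.linspace(0, 5, 7)
        pop = truth_params.beta["psa"][0] + truth_params.beta["psa"][1] * ts
        # posterior-mean profile equals the population trajectory up to MC
        # noise in the prior draws
        st_big = posterior_profile(truth_fit, rec, 1.0, condition_on_survival=False,
                                   mode="laplace", n_draws=4000, seed=1)
        np.testing.assert_allclose(st_big.profile("psa", ts), pop, atol=0.05)

    def test_identical_histories_identical_states(self, truth_fit):
        rec1 = make_record(pid="X", psa=[(0.0, 6.0), (1.0, 7.0)])
        rec2 = make_record(pid="Y", psa=[(0.0, 6.0), (1.0, 7.0)])
        s1 = posterior_profile(truth_fit, rec1, 1.5, seed=5)
        s2 = posterior_profile(truth_fit, rec2, 1.5, seed=5)
        np.testing.assert_array_equal(s1.b_draws, s2.b_draws)

    def test_landmark_before_first_observation_warns(self, truth_fit, caplog):
        rec = make_record(psa=[(2.0, 6.0)])
        with caplog.at_level("WARNING"):
            st = posterior_profile(truth_fit, rec, 1.0, condition_on_survival=False,
                                   mode="laplace", seed=0)
        assert "population" in caplog.text
        np.testing.assert_allclose(st.ranef_mean, 0.0, atol=1e-12)

    def test_shrinkage_monotone_in_data(self, truth_params):
        """Posterior covariance non-increasing (Loewner order) as nested
        observations accumulate."""
        fit = point_fit(truth_params)
        rng = np.random.default_rng(0)
        t_all = np.linspace(0, 4, 9)
        y_all = 6.0 * 2 ** (0.05 * t_all) * 2 ** rng.normal(0, 0.1, t_all.size)
        prev = None
        for k in range(1, t_all.size + 1):
            rec = make_record(psa=list(zip(t_all[:k], y_all[:k])))
            st = posterior_profile(fit, rec, 5.0, condition_on_survival=False,
                                   mode="laplace", seed=0)
            if prev is not None:
                eig = np.linalg.eigvalsh(prev - st.ranef_cov)
                assert eig.min() > -1e-9
            prev = st.ranef_cov

    def test_population_mean_observation_never_repels(self, truth_params):
        """Adding a baseline observation exactly at the population mean can
        only shrink the intercept estimate toward zero."""
        fit = point_fit(truth_params)
        mu0 = 2.0 ** truth_params.beta["psa"][0]
        rec1 = make_record(psa=[(0.0, 8.0)])
        st1 = posterior_profile(fit, rec1, 1.0, condition_on_survival=False,
                                mode="laplace", seed=0)
        rec2 = make_record(psa=[(0.0, 8.0), (0.0001, mu0)])
        st2 = posterior_profile(fit, rec2, 1.0, condition_on_survival=False,
                                mode="laplace", seed=0)
        assert abs(st2.ranef_mean[0]) <= abs(st1.ranef_mean[0]) + 1e-12


def make_state(beta_psa, b=None, basis=None, n_draws=1):
    params = ModelParams(
        beta={
            "psa": np.asarray(beta_psa, dtype=float),
            "volume": np.array([5.5, 0.0]),
            "mri_lesion": np.array([0.0, 0.0]),
            "benign": np.array([0.0, 0.0]),
        },
        sigma={"psa": 0.1, "volume": 0.1},
        ranef_cov=np.eye(6) * 0.01,
        alpha=np.zeros(6),
        h0=np.array([0.1]),
        knots=np.empty(0),
    )
    draws = ParamDraws.from_params(params, n_draws)
    bd = np.zeros((n_draws, 6)) if b is None else np.tile(b, (n_draws, 1))
    submodels = {}
    if basis is not None:
        submodels["psa"] = SubmodelSpec("psa", time_basis=basis)
        draws.beta["psa"] = np.tile(beta_psa, (n_draws, 1))
    return PatientState(
        patient_id="S", landmark_time_y=0.0, age_at_diagnosis=65.0,
        draws=draws, b_draws=bd, ranef_mean=bd[0], ranef_cov=np.eye(6),
        submodels=submodels,
    )


class TestVelocity:
    def test_flat_profile_zero_velocity(self):
        st = make_state([3.0, 0.0])
        assert instantaneous_velocity(st, 2.0)[0] == 0.0

    def test_doubling_per_year_velocity_one(self):
        st = make_state([3.0, 1.0])
        assert instantaneous_velocity(st, 2.0)[0] == pytest.approx(1.0)

    def test_spline_derivative_matches_finite_difference(self):
        basis = TimeBasis("nspline", knots=(0.0, 1.5, 3.0, 6.0))
        rng = np.random.default_rng(4)
        coef = rng.normal(0, 0.5, basis.n_coef)
        st = make_state(coef, basis=basis)
        h = 1e-5
        for t in (0.5, 2.0, 4.7):
            fd = (st.profile("psa", t + h)[0] - st.profile("psa", t - h)[0]) / (2 * h)
            assert instantaneous_velocity(st, t)[0] == pytest.approx(fd, abs=1e-6)


def test_error_free_rich_sampling_recovers_trajectory(truth_params):
    """With dense, nearly noise-free sampling, the fitted profile reproduces
    the patient's true trajectory."""
    p = truth_params.copy()
    p.sigma["psa"] = 1e-3
    fit = point_fit(p)
    b0, b1 = 0.4, 0.05
    ts = np.linspace(0, 5, 21)
    y = 2.0 ** (p.beta["psa"][0] + b0 + (p.beta["psa"][1] + b1) * ts)
    rec = make_record(psa=list(zip(ts, y)))
    st = posterior_profile(fit, rec, 5.0, condition_on_survival=False,
                           mode="laplace", seed=0)
    grid = np.linspace(0, 5, 11)
    true_prof = p.beta["psa"][0] + b0 + (p.beta["psa"][1] + b1) * grid
    np.testing.assert_allclose(st.profile("psa", grid), true_prof, atol=1e-3)
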