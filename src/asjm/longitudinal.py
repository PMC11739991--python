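"""Mixed-effects longitudinal submodels and patient-specific profiles.

Each of the four channels (log2-PSA, log2-volume, MRI suspicious lesion,
benign biopsy) follows a generalized linear mixed model sharing one
patient-level random-effects vector.  Given a fitted joint model and a
patient's history up to a landmark time, this module computes the
posterior of the patient's random effects -- by default conditioned on
being event-free at the landmark, as the joint model requires -- and
exposes the fitted (BLUP-style) channel profiles together with the exact
analytic derivative of the fitted log2-PSA profile, the instantaneous
PSA velocity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._core import (
    BINARY_CHANNELS,
    GAUSSIAN_CHANNELS,
    LONG_CHANNELS,
    N_RANEF,
    RANEF_INDEX,
    ModelParams,
    ParamDraws,
    PatientRecord,
    SubmodelSpec,
    TimeBasis,
    benign_from_gg,
    cumhaz_draws,
    int_exp_moments,
    linpred_coefs_draws,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SubmodelSpec",
    "TimeBasis",
    "DesignMatrices",
    "PatientState",
    "build_design",
    "posterior_profile",
    "instantaneous_velocity",
]


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrices:
    """Aligned response/design structures for one channel across a cohort."""

    channel: str
    y: np.ndarray  # transformed responses
    t: np.ndarray  # observation times (years)
    X: np.ndarray  # fixed-effects design (n_obs, p)
    Z: np.ndarray  # random-effects design (n_obs, len(random_effect_indices))
    patient_index: np.ndarray  # row -> position in the records list
    patient_ids: list[str]
    random_effect_indices: tuple[int, ...]


def _channel_raw(record: PatientRecord, channel: str):
    """Times and (transform-ready) values of a model channel from a record."""
    if channel == "benign":
        t, gg = record.channel("biopsy_gg")
        keep = gg < 2  # the reclassifying biopsy is not a benign-channel outcome
        return t[keep], benign_from_gg(gg[keep])
    return record.channel(channel)


def build_design(records: list[PatientRecord], spec: SubmodelSpec) -> DesignMatrices:
    """Stack one channel's observations into response and design arrays.

    Applies the log2 transform for continuous channels; raises with the
    offending patient and time if a nonpositive value cannot be
    transformed.  Empty channels yield empty (but well-shaped) arrays.
    """
    ts, ys, idx = [], [], []
    for i, r in enumerate(records):
        t, v = _channel_raw(r, spec.channel)
        if spec.transform == "log2":
            if np.any(v <= 0):
                bad_t = t[v <= 0][0]
                raise ValueError(
                    f"patient {r.patient_id}: nonpositive {spec.channel} value at "
                    f"t={bad_t} cannot be log2-transformed"
                )
            v = np.log2(v)
        ts.append(t)
        ys.append(v)
        idx.append(np.full(t.size, i))
    t = np.concatenate(ts) if ts else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    index = np.concatenate(idx).astype(int) if idx else np.empty(0, dtype=int)
    X = spec.time_basis.design(t) if t.size else np.empty((0, spec.time_basis.n_coef))
    zi = spec.random_effect_indices
    if len(zi) == 2:
        Z = np.stack([np.ones_like(t), t], axis=-1)
    else:
        Z = np.ones((t.size, 1))
    return DesignMatrices(
        channel=spec.channel,
        y=y,
        t=t,
        X=X,
        Z=Z,
        patient_index=index,
        patient_ids=[r.patient_id for r in records],
        random_effect_indices=zi,
    )


# ---------------------------------------------------------------------------
# Per-patient data up to a landmark
# ---------------------------------------------------------------------------


@dataclass
class _PatientData:
    """One patient's channel observations truncated at a landmark time."""

    t: dict[str, np.ndarray]
    y: dict[str, np.ndarray]
    X: dict[str, np.ndarray]
    n_obs: int


def _patient_data(
    record: PatientRecord, landmark: float, submodels: dict[str, SubmodelSpec]
) -> _PatientData:
    t, y, X = {}, {}, {}
    n = 0
    for ch in LONG_CHANNELS:
        tt, vv = _channel_raw(record, ch)
        keep = tt <= landmark + 1e-9
        tt, vv = tt[keep], vv[keep]
        if ch in GAUSSIAN_CHANNELS:
            if np.any(vv <= 0):
                raise ValueError(
                    f"patient {record.patient_id}: nonpositive {ch} value"
                )
            vv = np.log2(vv)
        t[ch], y[ch] = tt, vv
        basis = submodels[ch].time_basis
        X[ch] = basis.design(tt) if tt.size else np.empty((0, basis.n_coef))
        n += tt.size
    return _PatientData(t=t, y=y, X=X, n_obs=n)


# ---------------------------------------------------------------------------
# Random-effects posterior: Laplace approximation and MH refinement
# ---------------------------------------------------------------------------


def _surv_weight_vectors(alpha: np.ndarray):
    """How the random-effects vector enters (a, c) of lp(t) = a + c t."""
    w_a = np.array([alpha[1], alpha[2], alpha[3], 0.0, alpha[4], alpha[5]])
    w_c = np.array([0.0, alpha[1], 0.0, alpha[3], 0.0, 0.0])
    return w_a, w_c


def _laplace(
    params: ModelParams,
    data: _PatientData,
    age: float,
    surv_time: float | None,
):
    """Mode and covariance of p(b | data[, event-free to surv_time]).

    Newton iterations on the concave log posterior; the survival term's
    gradient and Hessian use the closed-form moments of the piecewise-
    exponential cumulative hazard (linear time bases only).
    """
    Sigma_inv = np.linalg.inv(params.ranef_cov)
    edges = np.concatenate([[0.0], params.knots, [np.inf]])
    w_a, w_c = _surv_weight_vectors(params.alpha)

    def parts(b):
        logp = -0.5 * b @ Sigma_inv @ b
        grad = -Sigma_inv @ b
        hess = Sigma_inv.copy()
        for ch in LONG_CHANNELS:
            tt, yy, XX = data.t[ch], data.y[ch], data.X[ch]
            if tt.size == 0:
                continue
            zi = RANEF_INDEX[ch]
            Z = np.stack([np.ones_like(tt), tt], axis=-1) if len(zi) == 2 else np.ones((tt.size, 1))
            eta = XX @ params.beta[ch] + Z @ b[list(zi)]
            if ch in GAUSSIAN_CHANNELS:
                s2 = params.sigma[ch] ** 2
                r = yy - eta
                logp += -0.5 * np.sum(r * r) / s2
                g = Z.T @ r / s2
                h = Z.T @ Z / s2
            else:
                p = 1.0 / (1.0 + np.exp(-eta))
                logp += np.sum(yy * eta - np.logaddexp(0.0, eta))
                g = Z.T @ (yy - p)
                h = (Z * (p * (1 - p))[:, None]).T @ Z
            for a_, ia in enumerate(zi):
                grad[ia] += g[a_]
                for b_, ib in enumerate(zi):
                    hess[ia, ib] += h[a_, b_]
        if surv_time is not None and surv_time > 0:
            a0, c0 = _point_lp_coefs(params, b, age)
            H = G1 = G2 = 0.0
            for k in range(params.h0.size):
                lo, hi = min(edges[k], surv_time), min(edges[k + 1], surv_time)
                if hi <= lo:
                    continue
                F0, F1, F2 = int_exp_moments(c0, lo, hi)
                H += params.h0[k] * np.exp(a0) * F0
                G1 += params.h0[k] * np.exp(a0) * F1
                G2 += params.h0[k] * np.exp(a0) * F2
            logp += -H
            grad += -(H * w_a + G1 * w_c)
            hess += (
                H * np.outer(w_a, w_a)
                + G1 * (np.outer(w_a, w_c) + np.outer(w_c, w_a))
                + G2 * np.outer(w_c, w_c)
            )
        return logp, grad, hess

    b = np.zeros(N_RANEF)
    logp, grad, hess = parts(b)
    for _ in range(50):
        step = np.linalg.solve(hess, grad)
        scale = 1.0
        for _ in range(30):
            b_new = b + scale * step
            lp_new, g_new, h_new = parts(b_new)
            if lp_new >= logp - 1e-12:
                break
            scale *= 0.5
        moved = np.max(np.abs(b_new - b))
        b, logp, grad, hess = b_new, lp_new, g_new, h_new
        if moved < 1e-10:
            break
    cov = np.linalg.inv(hess)
    return b, cov


def _point_lp_coefs(params: ModelParams, b: np.ndarray, age: float):
    from ._core import linpred_coefs

    a, c = linpred_coefs(params, b[None, :], np.array([age]))
    return float(a[0]), float(c[0])


def _b_logpost_draws(
    b: np.ndarray,
    data: _PatientData,
    draws: ParamDraws,
    age: float,
    surv_time: float | None,
) -> np.ndarray:
    """Unnormalised log posterior of b (S,6) per parameter draw."""
    sol = np.linalg.solve(draws.ranef_cov, b[..., None])[..., 0]
    logp = -0.5 * np.einsum("si,si->s", b, sol)
    # determinant term matters because the covariance differs per draw
    sign, logdet = np.linalg.slogdet(draws.ranef_cov)
    logp -= 0.5 * logdet
    for ch in LONG_CHANNELS:
        tt, yy, XX = data.t[ch], data.y[ch], data.X[ch]
        if tt.size == 0:
            continue
        zi = RANEF_INDEX[ch]
        eta = draws.beta[ch] @ XX.T  # (S, n)
        if len(zi) == 2:
            eta = eta + b[:, zi[0]][:, None] + b[:, zi[1]][:, None] * tt[None, :]
        else:
            eta = eta + b[:, zi[0]][:, None]
        if ch in GAUSSIAN_CHANNELS:
            s = draws.sigma[ch][:, None]
            r = yy[None, :] - eta
            logp += np.sum(-0.5 * (r / s) ** 2 - np.log(s), axis=1)
        else:
            logp += np.sum(yy[None, :] * eta - np.logaddexp(0.0, eta), axis=1)
    if surv_time is not None and surv_time > 0:
        a, c = linpred_coefs_draws(draws, b, age)
        logp -= cumhaz_draws(draws, a, c, surv_time)
    return logp


def _sample_b(
    data: _PatientData,
    draws: ParamDraws,
    age: float,
    surv_time: float | None,
    rng: np.random.Generator,
    mode: str = "mcmc",
    n_steps: int = 60,
):
    """One random-effects draw per parameter draw, given patient history.

    ``laplace`` draws from the Gaussian approximation at the posterior
    mean of the parameters; ``mcmc`` (default) refines those starting
    points with a Metropolis random walk targeting each draw's exact
    conditional posterior.
    """
    mean_params = draws.mean_params()
    bhat, cov = _laplace(mean_params, data, age, surv_time)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(N_RANEF))
    S = draws.n_draws
    if mode == "laplace":
        b = bhat[None, :] + rng.standard_normal((S, N_RANEF)) @ L.T
        return b, bhat, cov
    if mode != "mcmc":
        raise ValueError(f"unknown sampling mode {mode!r}")
    b = bhat[None, :] + rng.standard_normal((S, N_RANEF)) @ L.T
    logp = _b_logpost_draws(b, data, draws, age, surv_time)
    scale = 2.4 / np.sqrt(N_RANEF)
    for _ in range(n_steps):
        prop = b + scale * (rng.standard_normal((S, N_RANEF)) @ L.T)
        logp_prop = _b_logpost_draws(prop, data, draws, age, surv_time)
        acc = np.log(rng.random(S)) < (logp_prop - logp)
        b[acc] = prop[acc]
        logp[acc] = logp_prop[acc]
    return b, bhat, cov


# ---------------------------------------------------------------------------
# PatientState
# ---------------------------------------------------------------------------


@dataclass
class PatientState:
    """Posterior of a patient's random effects at a landmark time.

    Built from all observations with time <= landmark (and, by default,
    the information that the patient was still event-free then).  The
    profile evaluators return fitted values on the linear-predictor scale
    (log2 for PSA/volume, logit for the binary channels); ``velocity`` is
    the exact derivative of the fitted log2-PSA profile.
    """

    patient_id: str
    landmark_time_y: float
    age_at_diagnosis: float
    draws: ParamDraws
    b_draws: np.ndarray  # (S, 6)
    ranef_mean: np.ndarray
    ranef_cov: np.ndarray
    submodels: dict[str, SubmodelSpec] = field(default_factory=dict)
    conditioned_on_survival: bool = True

    def profile(self, channel: str, t, per_draw: bool = False):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        spec = self.submodels.get(channel, SubmodelSpec(channel))
        X = spec.time_basis.design(t)
        eta = self.draws.beta[channel] @ X.T  # (S, len(t))
        zi = RANEF_INDEX[channel]
        if len(zi) == 2:
            eta = eta + self.b_draws[:, zi[0]][:, None] + self.b_draws[:, zi[1]][:, None] * t
        else:
            eta = eta + self.b_draws[:, zi[0]][:, None]
        return eta if per_draw else eta.mean(axis=0)

    def velocity(self, t, per_draw: bool = False):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        spec = self.submodels.get("psa", SubmodelSpec("psa"))
        dX = spec.time_basis.deriv(t)
        dv = self.draws.beta["psa"] @ dX.T + self.b_draws[:, 1][:, None]
        return dv if per_draw else dv.mean(axis=0)


def posterior_profile(
    fit,
    record: PatientRecord,
    landmark_time_y: float,
    *,
    condition_on_survival: bool = True,
    mode: str = "mcmc",
    n_draws: int | None = None,
    seed: int | None = None,
) -> PatientState:
    """Patient-specific BLUP-style state given history up to a landmark.

    ``fit`` is a converged joint-model fit (or a point-mass fit built
    from known parameters).  The posterior of the random effects uses all
    channel observations up to the landmark and, unless switched off, the
    event-free status at the landmark.  With no observations the state
    shrinks fully to the population (prior) distribution.
    """
    if landmark_time_y < 0:
        raise ValueError("landmark_time_y must be >= 0")
    submodels = {s.channel: s for s in fit.spec.submodels}
    if condition_on_survival and any(
        s.time_basis.kind != "linear" for s in submodels.values()
    ):
        raise NotImplementedError(
            "survival conditioning requires linear time bases"
        )
    data = _patient_data(record, landmark_time_y, submodels)
    obs_times = np.concatenate([v for v in data.t.values()]) if data.n_obs else np.empty(0)
    all_times = [t for t, _, _ in record.observations]
    if all_times and data.n_obs == 0 and landmark_time_y < min(all_times):
        logger.warning(
            "patient %s: landmark %.3g precedes the first observation; "
            "returning the population (prior) state",
            record.patient_id,
            landmark_time_y,
        )
    draws = fit.param_draws()
    rng = np.random.default_rng(seed)
    if n_draws is not None and n_draws != draws.n_draws:
        idx = rng.choice(draws.n_draws, size=n_draws, replace=True)
        draws = draws.select(idx)
    surv_time = landmark_time_y if condition_on_survival else None
    b, bhat, cov = _sample_b(data, draws, record.age_at_diagnosis, surv_time, rng, mode=mode)
    return PatientState(
        patient_id=record.patient_id,
        landmark_time_y=landmark_time_y,
        age_at_diagnosis=record.age_at_diagnosis,
        draws=draws,
        b_draws=b,
        ranef_mean=bhat,
        ranef_cov=cov,
        submodels=submodels,
        conditioned_on_survival=condition_on_survival,
    )


def instantaneous_velocity(state: PatientState, t) -> np.ndarray:
    """Instantaneous log2-PSA velocity (per year) of the fitted profile.

    Exact analytic derivative of the basis expansion; a profile with PSA
    doubling every year has velocity 1.0.
    """
    return state.velocity(t)
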