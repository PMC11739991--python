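"""Landmark-conditional dynamic risk prediction and biopsy decisions.

Given a fitted joint model and a patient's accumulated history, the
predicted risk over a horizon is

    risk(t, t+h) = 1 - E[ S(t+h | b, theta) / S(t | b, theta) ]

with the expectation over the joint posterior of the model parameters
and the patient's random effects given all observations up to the
landmark t and event-free survival to t.  The risk updates as new
measurements arrive, and a threshold turns it into a defer/biopsy
decision (biopsy at or above the threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._core import (
    ParamDraws,
    PatientRecord,
    benign_from_gg,
    cumhaz_draws,
    linpred_coefs_draws,
)
from .longitudinal import PatientState, posterior_profile

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicRisk",
    "BiopsyDecision",
    "dynamic_risk",
    "update_and_repredict",
    "decide_biopsy",
    "conditional_risk_draws",
    "predict_risks",
]


@dataclass(frozen=True)
class DynamicRisk:
    """Conditional reclassification risk over (landmark, landmark+horizon].

    ``risk`` is the posterior mean; ``ci_low``/``ci_high`` the 2.5/97.5
    percentiles over posterior draws of the conditional probability.
    """

    patient_id: str
    landmark_time_y: float
    horizon_y: float
    risk: float
    ci_low: float
    ci_high: float
    n_draws: int


@dataclass(frozen=True)
class BiopsyDecision:
    """Audit record of a threshold decision (biopsy iff risk >= threshold)."""

    patient_id: str
    decision: str  # "biopsy" | "defer"
    risk: float
    threshold: float
    landmark_time_y: float
    horizon_y: float


def _count_mode_lp(draws: ParamDraws, b: np.ndarray, age: float, n_count: float):
    """(a, c) when the hazard uses the raw negative-biopsy count, frozen at
    its landmark value (future biopsy outcomes are undefined under a
    deferral decision)."""
    al = draws.alpha
    cen = draws.centers
    bp, bv = draws.beta["psa"], draws.beta["volume"]
    bl = draws.beta["mri_lesion"]
    a = (
        al[:, 0] * (age - cen[0])
        + al[:, 1] * (bp[:, 0] + b[:, 0] - cen[1])
        + al[:, 2] * (bp[:, 1] + b[:, 1] - cen[2])
        + al[:, 3] * (bv[:, 0] + b[:, 2] - cen[3])
        + al[:, 4] * (bl[:, 0] + b[:, 4] - cen[4])
        + al[:, 5] * (n_count - cen[5])
    )
    c = (
        al[:, 1] * (bp[:, 1] + b[:, 1])
        + al[:, 3] * (bv[:, 1] + b[:, 3])
        + al[:, 4] * bl[:, 1]
    )
    return a, c


def conditional_risk_draws(
    state: PatientState,
    horizon_y: float,
    count_mode: bool = False,
    n_count: float = 0.0,
) -> np.ndarray:
    """Per-draw conditional risk 1 - S(t+h)/S(t) from a patient state.

    Exact per draw under the linear time bases (closed-form piecewise-
    exponential cumulative hazard), hence exactly 0 at horizon 0 and
    exactly non-decreasing in the horizon for every draw.
    """
    if horizon_y < 0:
        raise ValueError("horizon must be >= 0")
    t0 = state.landmark_time_y
    draws = state.draws
    if count_mode:
        a, c = _count_mode_lp(draws, state.b_draws, state.age_at_diagnosis, n_count)
    else:
        a, c = linpred_coefs_draws(draws, state.b_draws, state.age_at_diagnosis)
    H0 = cumhaz_draws(draws, a, c, np.full(a.shape, t0))
    H1 = cumhaz_draws(draws, a, c, np.full(a.shape, t0 + horizon_y))
    return 1.0 - np.exp(-(H1 - H0))


def _negative_biopsy_count(record: PatientRecord, landmark: float) -> float:
    t, gg = record.channel("biopsy_gg")
    keep = (t <= landmark + 1e-9) & (gg < 2)
    return float(benign_from_gg(gg[keep]).sum())


def dynamic_risk(
    fit,
    record: PatientRecord,
    landmark_time_y: float,
    horizon_y: float,
    *,
    n_draws: int = 500,
    seed: int | None = None,
    mode: str = "mcmc",
) -> DynamicRisk:
    """Predicted reclassification risk in (landmark, landmark+horizon].

    Conditions on the patient's observations up to the landmark and on
    being event-free there; Monte Carlo over >= 500 posterior draws by
    default, reproducible given ``seed``.
    """
    if horizon_y < 0:
        raise ValueError("horizon_y must be >= 0")
    if record.event_time_y is not None and record.event_time_y <= landmark_time_y + 1e-9:
        raise ValueError(
            f"patient {record.patient_id} is not event-free at landmark {landmark_time_y}"
        )
    fit_horizon = getattr(fit, "horizon_y", None)
    if fit_horizon is not None and landmark_time_y > fit_horizon:
        raise ValueError(
            f"landmark {landmark_time_y} beyond the model's follow-up horizon "
            f"({fit_horizon:.2f} y)"
        )
    state = posterior_profile(
        fit, record, landmark_time_y, condition_on_survival=True,
        mode=mode, n_draws=n_draws, seed=seed,
    )
    count_mode = fit.spec.benign_covariate_mode == "count"
    r = conditional_risk_draws(
        state, horizon_y, count_mode=count_mode,
        n_count=_negative_biopsy_count(record, landmark_time_y),
    )
    return DynamicRisk(
        patient_id=record.patient_id,
        landmark_time_y=landmark_time_y,
        horizon_y=horizon_y,
        risk=float(r.mean()),
        ci_low=float(np.percentile(r, 2.5)),
        ci_high=float(np.percentile(r, 97.5)),
        n_draws=int(r.size),
    )


def update_and_repredict(
    fit,
    record: PatientRecord,
    new_observations: list[tuple[float, str, float]],
    landmark_time_y: float,
    horizon_y: float = 1.5,
    **kwargs,
) -> DynamicRisk:
    """Merge new observations into the record and re-predict.

    New observations must be timestamped at or before the landmark.
    Duplicate (time, channel) entries among the new observations, or a
    conflict with an existing observation's value, are validation
    failures; re-appending an observation already present verbatim is a
    no-op (idempotent).
    """
    seen = set()
    for t, ch, v in new_observations:
        if t > landmark_time_y + 1e-9:
            raise ValueError(f"new observation at t={t} is after the landmark")
        if (t, ch) in seen:
            raise ValueError(f"duplicate (time, channel) = ({t}, {ch}) in new observations")
        seen.add((t, ch))
    merged = list(record.observations)
    existing = {(t, ch): v for t, ch, v in record.observations}
    for t, ch, v in new_observations:
        if (t, ch) in existing:
            if not np.isclose(existing[(t, ch)], v):
                raise ValueError(
                    f"conflicting value for ({t}, {ch}): {existing[(t, ch)]} vs {v}"
                )
            continue  # already present verbatim
        merged.append((t, ch, v))
    merged.sort(key=lambda o: (o[0], o[1]))
    updated = PatientRecord(
        patient_id=record.patient_id,
        age_at_diagnosis=record.age_at_diagnosis,
        observations=merged,
        event_time_y=record.event_time_y,
        censor_time_y=record.censor_time_y,
    )
    return dynamic_risk(fit, updated, landmark_time_y, horizon_y, **kwargs)


def decide_biopsy(risk: DynamicRisk, threshold: float) -> BiopsyDecision:
    """Threshold rule: biopsy iff risk >= threshold (boundary inclusive)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    decision = "biopsy" if risk.risk >= threshold else "defer"
    return BiopsyDecision(
        patient_id=risk.patient_id,
        decision=decision,
        risk=risk.risk,
        threshold=threshold,
        landmark_time_y=risk.landmark_time_y,
        horizon_y=risk.horizon_y,
    )


def predict_risks(
    fit,
    records: list[PatientRecord],
    landmark_time_y: float,
    horizon_y: float,
    *,
    n_draws: int = 300,
    seed: int | None = None,
    mode: str = "mcmc",
) -> pd.DataFrame:
    """Risks for every patient still at risk at the landmark.

    Patients whose follow-up ended at or before the landmark are skipped.
    Returns a frame with patient_id, risk, ci bounds, and the patient's
    observed follow-up (useful for downstream evaluation).
    """
    rows = []
    rng = np.random.default_rng(seed)
    for rec in records:
        if rec.observed_time_y <= landmark_time_y + 1e-9:
            continue
        dr = dynamic_risk(
            fit, rec, landmark_time_y, horizon_y,
            n_draws=n_draws, seed=int(rng.integers(2**31 - 1)), mode=mode,
        )
        rows.append(
            {
                "patient_id": rec.patient_id,
                "landmark_time_y": landmark_time_y,
                "horizon_y": horizon_y,
                "risk": dr.risk,
                "ci_low": dr.ci_low,
                "ci_high": dr.ci_high,
                "observed_time_y": rec.observed_time_y,
                "event": rec.status == "event",
            }
        )
    return pd.DataFrame(rows)
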