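"""Performance assessment of dynamic risk predictions.

Covers prognostic discrimination (time-dependent AUC over a landmark
grid), threshold-based diagnostic accuracy normalised per 1000 biopsy
decisions, decision-curve net benefit expressed as net biopsies avoided
per 100 patients, calibration of predicted against observed incidence,
and baseline-hazard recalibration for transporting the model to a new
cohort.

Because reclassification is only observable at biopsies, the default
estimators restrict to patients whose status at the end of the
evaluation window is adjudicated (event detected within the window, or
follow-up extending past it); an inverse-probability-of-censoring
weighted AUC variant is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.stats.proportion import proportion_confint

from ._core import PatientRecord, cohort_arrays
from .longitudinal import _laplace, _patient_data
from .survival_joint import JointModelFit

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedMetricError",
    "ConfusionPer1000",
    "NetBenefitResult",
    "time_dependent_auc",
    "adjudicated_outcomes",
    "diagnostic_accuracy",
    "reconstruct_confusion_from_deferral",
    "net_biopsies_avoided",
    "calibration_curve",
    "recalibrate",
    "accuracy_table",
    "round_half_away",
]


class UndefinedMetricError(ValueError):
    """A metric has no value on this data (e.g. no cases in the window)."""


def round_half_away(x: float) -> int:
    """Nearest integer, halves away from zero (the convention needed to
    reproduce printed clinical-table arithmetic)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


# ---------------------------------------------------------------------------
# Time-dependent AUC
# ---------------------------------------------------------------------------


def time_dependent_auc(
    risks: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    landmark: float,
    window: float,
    ipcw: bool = False,
) -> float:
    """P(risk of a case > risk of a control) at a landmark.

    Cases experience the detected event in (landmark, landmark+window];
    controls are known event-free at landmark+window.  Only patients at
    risk at the landmark enter; ties in risk count 1/2.  With
    ``ipcw=True``, patients censored inside the window are retained
    through inverse-probability-of-censoring weights instead of being
    excluded.
    """
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    end = landmark + window
    at_risk = times > landmark + 1e-9
    risks, times, events = risks[at_risk], times[at_risk], events[at_risk]

    case = events & (times <= end + 1e-9)
    ctrl = times > end + 1e-9
    ctrl |= (~events) & (times >= end - 1e-9)

    if ipcw:
        cens_km = KaplanMeierFitter().fit(times, ~events)
        G = lambda t: np.maximum(  # noqa: E731
            np.asarray(cens_km.survival_function_at_times(t)), 1e-8
        )
        w_case = np.where(case, 1.0 / G(np.minimum(times, end)), 0.0)
        w_ctrl = np.where(ctrl, 1.0 / G(end), 0.0)
    else:
        w_case = case.astype(float)
        w_ctrl = ctrl.astype(float)

    if w_case.sum() == 0:
        raise UndefinedMetricError("no cases within the evaluation window")
    if w_ctrl.sum() == 0:
        raise UndefinedMetricError("no controls at the end of the evaluation window")

    ci = np.flatnonzero(w_case > 0)
    cj = np.flatnonzero(w_ctrl > 0)
    rc = risks[ci][:, None]
    rj = risks[cj][None, :]
    conc = (rc > rj) + 0.5 * (rc == rj)
    w = np.outer(w_case[ci], w_ctrl[cj])
    return float((conc * w).sum() / w.sum())


def adjudicated_outcomes(
    records: list[PatientRecord], landmark: float, window: float
):
    """(evaluable mask, event-within-window) for biopsy-adjudicated status.

    Evaluable: at risk at the landmark and either reclassified within
    (landmark, landmark+window] or followed event-free past the window.
    """
    T = np.array([r.observed_time_y for r in records])
    d = np.array([r.status == "event" for r in records])
    end = landmark + window
    at_risk = T > landmark + 1e-9
    case = d & (T <= end + 1e-9) & at_risk
    known_free = (T > end + 1e-9) | ((~d) & (T >= end - 1e-9))
    evaluable = at_risk & (case | known_free)
    return evaluable, case


# ---------------------------------------------------------------------------
# Confusion tables per 1000 biopsy decisions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionPer1000:
    """A threshold's confusion table normalised to 1000 biopsy decisions.

    Counts are fractional; a biopsy is "positive" when the predicted risk
    reaches the threshold, and the disease state is reclassification at
    the evaluation window.  ``biopsies_delayed`` (= tn + fn) and
    ``reclassifications_delayed`` (= fn) are the clinical bookkeeping
    columns; sens/spec/npv/ppv are percentages with Wilson 95% CIs where
    a cohort size is known.
    """

    threshold: float
    tp: float
    fp: float
    tn: float
    fn: float
    n_source: int | None = None  # actual decisions behind the per-1000 scaling

    def __post_init__(self):
        tot = self.tp + self.fp + self.tn + self.fn
        if not any(np.isnan([self.tp, self.fp, self.tn, self.fn])):
            if abs(tot - 1000.0) > 1e-6:
                raise ValueError(f"per-1000 counts must sum to 1000, got {tot}")

    @property
    def sens(self) -> float:
        return 100.0 * (self.tp / (self.tp + self.fn))

    @property
    def spec(self) -> float:
        return 100.0 * (self.tn / (self.tn + self.fp))

    @property
    def npv(self) -> float:
        return 100.0 * (self.tn / (self.tn + self.fn))

    @property
    def ppv(self) -> float:
        return 100.0 * (self.tp / (self.tp + self.fp))

    @property
    def prevalence_per_1000(self) -> float:
        return self.tp + self.fn

    @property
    def biopsies_delayed(self) -> float:
        return self.tn + self.fn

    @property
    def reclassifications_delayed(self) -> float:
        return self.fn

    def wilson_ci(self, which: str) -> tuple[float, float]:
        """Wilson 95% CI (percent) for sens/spec/npv/ppv, using the actual
        decision counts when known."""
        if self.n_source is None:
            raise ValueError("Wilson CI needs the source cohort size")
        scale = self.n_source / 1000.0
        num, den = {
            "sens": (self.tp, self.tp + self.fn),
            "spec": (self.tn, self.tn + self.fp),
            "npv": (self.tn, self.tn + self.fn),
            "ppv": (self.tp, self.tp + self.fp),
        }[which]
        lo, hi = proportion_confint(num * scale, den * scale, method="wilson")
        return 100.0 * lo, 100.0 * hi


def diagnostic_accuracy(
    risks: np.ndarray,
    outcomes: np.ndarray,
    thresholds,
) -> list[ConfusionPer1000]:
    """Threshold grid of per-1000 confusion tables.

    ``outcomes`` are adjudicated event indicators at the evaluation
    window for the same patients as ``risks``; a biopsy is indicated
    when risk >= threshold (boundary inclusive).
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold list must be nonempty")
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes, dtype=bool)
    n = risks.size
    if n == 0:
        raise ValueError("no evaluable patients")
    out = []
    for thr in thresholds:
        pos = risks >= thr
        tp = float(np.sum(pos & outcomes))
        fp = float(np.sum(pos & ~outcomes))
        fn = float(np.sum(~pos & outcomes))
        tn = float(np.sum(~pos & ~outcomes))
        f = 1000.0 / n
        out.append(
            ConfusionPer1000(
                threshold=float(thr), tp=tp * f, fp=fp * f, tn=tn * f, fn=fn * f,
                n_source=n,
            )
        )
    return out


def reconstruct_confusion_from_deferral(
    sens_pct: float, deferred_per_1000: float, fn_per_1000: float
) -> ConfusionPer1000:
    """Rebuild the full per-1000 confusion table from printed columns.

    Clinical tables print sensitivity, deferred biopsies per 1000 and
    delayed reclassifications per 1000; from these the prevalence and
    the remaining cells follow:  prevalence*1000 = fn / (1 - sens),
    tp = sens * prevalence * 1000, tn = deferred - fn,
    fp = 1000 - deferred - tp.
    """
    if fn_per_1000 > deferred_per_1000:
        raise ValueError("delayed reclassifications cannot exceed deferred biopsies")
    if not 0 < sens_pct <= 100:
        raise ValueError("sensitivity must be in (0, 100]")
    if sens_pct == 100:
        if fn_per_1000 > 0:
            raise ValueError("sensitivity 100% is inconsistent with delayed events")
        # prevalence is unidentified; only the deferral side is determined
        return ConfusionPer1000(
            threshold=float("nan"),
            tp=float("nan"),
            fp=float("nan"),
            tn=float(deferred_per_1000),
            fn=0.0,
        )
    s = sens_pct / 100.0
    prev1000 = fn_per_1000 / (1.0 - s)
    tp = s * prev1000
    tn = deferred_per_1000 - fn_per_1000
    fp = 1000.0 - deferred_per_1000 - tp
    return ConfusionPer1000(
        threshold=float("nan"), tp=tp, fp=fp, tn=tn, fn=float(fn_per_1000)
    )


# ---------------------------------------------------------------------------
# Decision-curve net benefit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetBenefitResult:
    """Net benefit of the model-guided biopsy policy at threshold pt.

    Net benefits are in net true positives per patient; the headline
    clinical quantity is ``net_biopsies_avoided_per_100`` versus a
    biopsy-for-all policy, using (1-pt)/pt as the exchange rate between
    false and true positives.
    """

    threshold_prob: float
    nb_model: float
    nb_all: float
    nb_none: float
    net_biopsies_avoided_per_100: float


def net_biopsies_avoided(confusion: ConfusionPer1000, pt: float) -> NetBenefitResult:
    if not 0.0 < pt < 1.0:
        raise ValueError("pt must be in (0, 1)")
    tp = confusion.tp / 1000.0
    fp = confusion.fp / 1000.0
    prev = confusion.prevalence_per_1000 / 1000.0
    ex = pt / (1.0 - pt)
    nb_model = tp - fp * ex
    nb_all = prev - (1.0 - prev) * ex
    avoided = 100.0 * (nb_model - nb_all) * (1.0 - pt) / pt
    return NetBenefitResult(
        threshold_prob=pt,
        nb_model=nb_model,
        nb_all=nb_all,
        nb_none=0.0,
        net_biopsies_avoided_per_100=avoided,
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibration_curve(
    risks: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    horizon: float,
    n_bins: int = 10,
):
    """Observed (Kaplan-Meier) vs mean predicted incidence per risk bin.

    ``times``/``events`` are follow-up from the prediction landmark.
    Returns (per-bin frame, (overall mean predicted, overall observed))
    -- the overall pair is the external-validation summary comparing the
    cohort's mean predicted risk with its observed incidence.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    edges = np.unique(np.quantile(risks, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # all risks identical: a single bin
        edges = np.array([edges[0], edges[0] + 1e-12])
    if edges.size - 1 < n_bins:
        logger.info("merged empty/duplicate calibration bins: %d -> %d",
                    n_bins, edges.size - 1)
    bins = np.clip(np.searchsorted(edges, risks, side="right") - 1, 0, edges.size - 2)
    rows = []
    for k in range(edges.size - 1):
        m = bins == k
        if m.sum() == 0:
            continue
        km = KaplanMeierFitter().fit(times[m], events[m])
        obs = float(1.0 - km.survival_function_at_times(horizon).iloc[0])
        ci = km.confidence_interval_survival_function_
        idx = ci.index.searchsorted(horizon, side="right") - 1
        lo = float(1.0 - ci.iloc[idx, 1]) if idx >= 0 else 0.0
        hi = float(1.0 - ci.iloc[idx, 0]) if idx >= 0 else 1.0
        rows.append(
            {
                "bin": k,
                "n": int(m.sum()),
                "mean_predicted": float(risks[m].mean()),
                "observed": obs,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    km_all = KaplanMeierFitter().fit(times, events)
    overall = (
        float(risks.mean()),
        float(1.0 - km_all.survival_function_at_times(horizon).iloc[0]),
    )
    return pd.DataFrame(rows), overall


# ---------------------------------------------------------------------------
# Recalibration
# ---------------------------------------------------------------------------


def recalibrate(fit: JointModelFit, new_records: list[PatientRecord]) -> JointModelFit:
    """Re-estimate the baseline-hazard scale on a new cohort.

    Association coefficients stay fixed; the proportional scale e^delta
    maximising the new cohort's event/censoring likelihood has the
    closed form delta = log(D / sum_i H_i) with D the event count and
    H_i each patient's expected cumulative hazard under the current fit
    (random effects at their Laplace posterior modes given that
    patient's longitudinal history).  Returns a new fit whose baseline
    hazard draws are scaled by e^delta.
    """
    from ._core import cumulative_hazard_linear, linpred_coefs

    arr = cohort_arrays(new_records, fit.spec.outcome_definition)
    D = int(arr.delta.sum())
    if D == 0:
        raise ValueError("new cohort has no events; cannot recalibrate")
    params = fit.posterior_mean_params()
    submodels = fit.spec.submodel
    H = np.empty(arr.n)
    for i, rec in enumerate(new_records):
        data = _patient_data(rec, arr.T[i], submodels)
        bhat, _ = _laplace(params, data, rec.age_at_diagnosis, surv_time=None)
        a, c = linpred_coefs(params, bhat[None, :], np.array([rec.age_at_diagnosis]))
        H[i] = float(np.asarray(cumulative_hazard_linear(params, a, c, arr.T[i])).ravel()[0])
    delta = float(np.log(D / H.sum()))
    new_draws = dict(fit.draws)
    new_draws["h0"] = fit.draws["h0"] * np.exp(delta)
    logger.info("recalibration: log baseline-hazard shift = %.4f", delta)
    return JointModelFit(
        spec=fit.spec,
        knots=fit.knots.copy(),
        draws=new_draws,
        diagnostics=fit.diagnostics,
        seed=fit.seed,
        config=fit.config,
        converged=fit.converged,
        b_draws=fit.b_draws,
        patient_ids=fit.patient_ids,
        centers=None if fit.centers is None else fit.centers.copy(),
        horizon_y=fit.horizon_y,
        recalibration_log_shift=delta,
    )


# ---------------------------------------------------------------------------
# Assembled accuracy table
# ---------------------------------------------------------------------------


def accuracy_table(
    risks: np.ndarray,
    outcomes: np.ndarray,
    thresholds,
) -> pd.DataFrame:
    """Threshold grid in the shape of a clinical accuracy table.

    Columns: threshold (%), sensitivity, specificity, NPV, PPV (each
    "pct (lo-hi)" with Wilson CIs), biopsies deferred and detected
    reclassifications delayed per 1000, and net biopsies avoided per
    100 patients at that threshold.
    """
    rows = []
    for conf in diagnostic_accuracy(risks, outcomes, thresholds):
        nb = net_biopsies_avoided(conf, conf.threshold)

        def fmt(which):
            val = getattr(conf, which)
            lo, hi = conf.wilson_ci(which)
            return (
                f"{round_half_away(val)} "
                f"({round_half_away(lo)}-{round_half_away(hi)})"
            )

        rows.append(
            {
                "threshold_pct": 100.0 * conf.threshold,
                "sensitivity": fmt("sens"),
                "specificity": fmt("spec"),
                "npv": fmt("npv"),
                "ppv": fmt("ppv"),
                "biopsies_delayed_per_1000": round_half_away(conf.biopsies_delayed),
                "reclassifications_delayed_per_1000": round_half_away(
                    conf.reclassifications_delayed
                ),
                "net_biopsies_avoided_per_100": round_half_away(
                    nb.net_biopsies_avoided_per_100
                ),
            }
        )
    return pd.DataFrame(rows)
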