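"""Evaluation procedures: bootstrap AUC confidence intervals, threshold
metrics, the slides-per-patient subsampling experiment, percentile
enrichment, and univariate odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .errors import EvaluationError

__all__ = ["EvalReport", "auc_with_ci", "sens_spec_at_sensitivity",
           "slides_per_patient_experiment", "percentile_enrichment",
           "odds_ratio_univariate"]


@dataclass
class EvalReport:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    n: int
    subgroup: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.auc <= 1.0 and self.ci_low <= self.ci_high):
            raise ValueError("inconsistent evaluation report")


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise EvaluationError("both classes must be present")


def auc_with_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
                patient_ids=None, subgroup: str | None = None) -> EvalReport:
    """Rank-based AUC (ties counted half) with a percentile bootstrap CI.

    Cases are resampled with replacement; when `patient_ids` are supplied,
    whole patients are resampled instead, since slides of one patient are
    not independent.  Resamples with a single class are redrawn.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    point = roc_auc_score(labels, scores)
    rng = np.random.default_rng(seed)
    boots = []
    if patient_ids is not None:
        patient_ids = np.asarray(patient_ids)
        uniq = np.unique(patient_ids)
        members = {p: np.flatnonzero(patient_ids == p) for p in uniq}
    attempts = 0
    while len(boots) < n_boot and attempts < 10 * n_boot:
        attempts += 1
        if patient_ids is None:
            idx = rng.integers(0, len(scores), len(scores))
        else:
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([members[p] for p in chosen])
        if len(np.unique(labels[idx])) < 2:
            continue
        boots.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EvalReport(float(point), float(lo), float(hi), n_boot,
                      len(scores), subgroup)


def sens_spec_at_sensitivity(scores, labels, target_sensitivity: float,
                             ) -> tuple[float, float, float]:
    """Largest threshold whose sensitivity reaches the target.

    Returns ``(threshold, sensitivity, specificity)`` achieved at that
    operating point (scores >= threshold called positive).
    """
    if target_sensitivity > 1.0:
        raise ValueError("target sensitivity cannot exceed 1")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    best = None
    for thr in np.unique(scores)[::-1]:          # descending candidates
        sens = float(np.mean(pos >= thr))
        if sens >= target_sensitivity:
            spec = float(np.mean(neg < thr))
            best = (float(thr), sens, spec)
            break
    if best is None:                              # degenerate: call all pos
        thr = float(np.min(scores))
        best = (thr, float(np.mean(pos >= thr)), float(np.mean(neg < thr)))
    return best


def slides_per_patient_experiment(slide_scores, patient_ids, patient_labels,
                                  n: int, n_reps: int = 1000,
                                  seed: int = 0) -> float:
    """Mean patient-level AUC when only `n` slides per patient are used.

    Restricted to patients with at least `n` slides; per repetition, `n`
    slides are sampled without replacement from each eligible patient,
    their scores averaged, and the patient-level AUC computed.  The mean
    AUC over `n_reps` repetitions is returned.
    """
    slide_scores = np.asarray(slide_scores, dtype=np.float64)
    patient_ids = np.asarray(patient_ids)
    labels = dict(zip(np.asarray(patient_labels.index)
                      if isinstance(patient_labels, pd.Series)
                      else np.unique(patient_ids),
                      np.asarray(patient_labels.values
                                 if isinstance(patient_labels, pd.Series)
                                 else patient_labels)))
    eligible = []
    for p in np.unique(patient_ids):
        idx = np.flatnonzero(patient_ids == p)
        if len(idx) >= n:
            eligible.append((p, idx))
    if not eligible:
        raise EvaluationError(f"no patient has at least {n} slides")
    y = np.array([labels[p] for p, _ in eligible])
    if len(np.unique(y)) < 2:
        raise EvaluationError("eligible patients cover a single class")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_reps)
    for rep in range(n_reps):
        means = [slide_scores[rng.choice(idx, size=n, replace=False)].mean()
                 for _, idx in eligible]
        aucs[rep] = roc_auc_score(y, means)
    return float(aucs.mean())


def percentile_enrichment(scores, labels, n_bins: int) -> pd.DataFrame:
    """Carrier proportion and odds ratio per equal-count score bin.

    Samples are ranked stably by score and split into `n_bins` equal-count
    bins; each bin's odds ratio is computed against the lowest bin from the
    2x2 table (0.5 added to zero cells)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(scores, kind="stable")
    bins = np.array_split(order, n_bins)
    rows = []
    a0 = labels[bins[0]].sum()
    b0 = len(bins[0]) - a0
    for k, idx in enumerate(bins):
        pos = int(labels[idx].sum())
        neg = len(idx) - pos
        if k == 0:
            oddsr = 1.0
        else:
            a, b, c, d = pos, neg, a0, b0
            if min(a, b, c, d) == 0:
                a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            oddsr = (a * d) / (b * c)
        rows.append({"bin": k, "n": len(idx),
                     "proportion_positive": pos / len(idx),
                     "odds_ratio_vs_lowest": float(oddsr)})
    return pd.DataFrame(rows)


def odds_ratio_univariate(feature, labels,
                          ) -> tuple[float, tuple[float, float], float]:
    """Odds ratio per unit of `feature` from a univariate logistic fit.

    Returns ``(OR, (ci_low, ci_high), p_value)`` with a Wald 95% CI on the
    log odds ratio.  Complete separation is flagged with an unbounded CI.
    """
    x = np.asarray(feature, dtype=np.float64)
    y = np.asarray(labels, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("feature is constant; odds ratio undefined")
    _check_two_classes(y)
    try:
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        beta, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
    except Exception:
        return np.inf, (0.0, np.inf), np.nan
    if not np.isfinite(se) or se > 50:          # quasi-separation
        return float(np.exp(beta)), (0.0, np.inf), float(p)
    return (float(np.exp(beta)),
            (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
            float(p))
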