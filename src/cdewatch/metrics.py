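"""Evaluation statistics for risk scores.

Discrimination (AUROC, AUPRC), stratified-bootstrap confidence intervals,
the DeLong paired AUROC comparison, Benjamini-Hochberg multiplicity
control, sensitivity-targeted operating points, and subgroup fairness
reporting.

AUROC uses the midrank Mann-Whitney convention throughout (ties count
half), which keeps the point estimate and the DeLong variance mutually
consistent.  AUPRC is average precision (step-wise interpolation over
recall change points).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_REPLICATES = 2000


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    return scores, labels


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties half)."""
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Average precision over the recall change points."""
    scores, labels = _check_scores_labels(scores, labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC undefined without positives")
    return float(average_precision_score(labels, scores))


def bootstrap_ci(metric, scores, labels, B: int = DEFAULT_BOOTSTRAP_REPLICATES,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile CI from class-stratified bootstrap resamples.

    Positives and negatives are resampled independently with replacement,
    so every replicate retains both classes.  A replicate on which the
    metric is undefined is redrawn (logged).
    """
    scores, labels = _check_scores_labels(scores, labels)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("stratified bootstrap requires both classes")
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    for b in range(B):
        for _attempt in range(100):
            idx = np.concatenate([
                rng.choice(pos, size=len(pos), replace=True),
                rng.choice(neg, size=len(neg), replace=True)])
            try:
                stats[b] = metric(scores[idx], labels[idx])
                break
            except ValueError:
                log.debug("metric undefined on replicate %d; redrawing", b)
        else:
            raise RuntimeError("metric undefined on 100 consecutive replicates")
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(stats, alpha)),
            float(np.quantile(stats, 1.0 - alpha)))


# --- DeLong ---------------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    """Midrank placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    ranks_all = rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - rankdata(neg)) / m
    return v10, v01


def auroc_variance(scores, labels) -> tuple[float, float]:
    """DeLong point estimate and sampling variance of one model's AUROC."""
    scores, labels = _check_scores_labels(scores, labels)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / len(v10)) + (np.var(v01, ddof=1) / len(v01))
    return auc, float(var)


@dataclass(frozen=True)
class DelongResult:
    auroc_a: float
    auroc_b: float
    delta: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """Paired DeLong comparison of two models scored on the same samples.

    The covariance of the two AUROCs comes from the empirical covariance
    of the placement values; two-sided p from the normal approximation.
    Identical score vectors give zero variance and p = 1 by convention.
    """
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, labels_b = _check_scores_labels(scores_b, labels)
    if len(scores_a) != len(scores_b):
        raise ValueError("paired comparison requires equal-length scores")
    if len(np.unique(labels)) < 2:
        raise ValueError("DeLong test requires both classes")
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    m, n = len(va10), len(va01)
    s10 = np.cov(np.stack([va10, vb10]), ddof=1)
    s01 = np.cov(np.stack([va01, vb01]), ddof=1)
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    delta = auc_a - auc_b
    if var <= 0 or math.isclose(var, 0.0):
        z = 0.0 if math.isclose(delta, 0.0, abs_tol=1e-12) else math.inf * np.sign(delta)
        p = 1.0 if z == 0.0 else 0.0
    else:
        z = delta / math.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return DelongResult(auroc_a=auc_a, auroc_b=auc_b, delta=delta,
                        z=float(z), p=p)


def unpaired_auroc_test(scores_a, labels_a, scores_b, labels_b
                        ) -> DelongResult:
    """Two-sample AUROC z-test for disjoint groups.

    Each group's AUROC variance is the DeLong single-model variance; the
    groups are independent, so the variances add.  Used for subgroup
    comparisons, where the paired construction does not apply.
    """
    auc_a, var_a = auroc_variance(scores_a, labels_a)
    auc_b, var_b = auroc_variance(scores_b, labels_b)
    delta = auc_a - auc_b
    var = var_a + var_b
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = delta / math.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return DelongResult(auroc_a=auc_a, auroc_b=auc_b, delta=delta,
                        z=float(z), p=p)


def bh_adjust(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and the rejection set at q < alpha."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


# --- operating points ------------------------------------------------------

@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    nna: float  # samples alerted per true positive, 1 / PPV


def operating_points(scores, labels, sensitivity_targets) -> list[OperatingPoint]:
    """Largest threshold reaching each sensitivity target (score >= threshold fires).

    Sensitivity is non-increasing in the threshold, so the largest
    qualifying threshold minimizes false positives at the required
    sensitivity.
    """
    scores, labels = _check_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("operating points require both classes")
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    out = []
    for target in sensitivity_targets:
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"unreachable sensitivity target {target}")
        chosen = None
        for thr in thresholds:
            pred = scores >= thr
            tp = int((pred & (labels == 1)).sum())
            if tp / n_pos >= target:
                fp = int((pred & (labels == 0)).sum())
                chosen = (thr, tp, fp)
                break
        thr, tp, fp = chosen
        sens = tp / n_pos
        spec = 1.0 - fp / n_neg
        ppv = tp / (tp + fp) if (tp + fp) else 0.0
        nna = 1.0 / ppv if ppv > 0 else math.inf
        out.append(OperatingPoint(threshold=float(thr), sensitivity=sens,
                                  specificity=spec, ppv=ppv, nna=nna))
    return out


# --- subgroup fairness -----------------------------------------------------

def fairness_report(scored: pd.DataFrame, tag_columns: list[str],
                    reference: dict, B: int = DEFAULT_BOOTSTRAP_REPLICATES,
                    seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Per-subgroup AUROC with CIs and unpaired tests vs. a reference group.

    ``scored`` needs ``score`` and ``label`` columns plus the tag columns;
    ``reference`` maps each tag column to its reference level.  Subgroups
    with a single outcome class are flagged not-evaluable and excluded
    from the BH family.
    """
    rows = []
    for tag in tag_columns:
        ref_level = reference[tag]
        ref = scored[scored[tag] == ref_level]
        ref_ok = ref["label"].nunique() == 2
        for level, grp in scored.groupby(tag, sort=True, observed=True):
            evaluable = grp["label"].nunique() == 2
            row = {"tag": tag, "level": level, "n": len(grp),
                   "is_reference": level == ref_level,
                   "evaluable": bool(evaluable),
                   "auroc": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                   "delta_vs_ref": np.nan, "z": np.nan, "p": np.nan}
            if evaluable:
                row["auroc"] = auroc(grp["score"], grp["label"])
                row["ci_lo"], row["ci_hi"] = bootstrap_ci(
                    auroc, grp["score"].to_numpy(), grp["label"].to_numpy(),
                    B=B, seed=seed)
                if ref_ok and level != ref_level:
                    res = unpaired_auroc_test(
                        grp["score"], grp["label"], ref["score"], ref["label"])
                    row.update(delta_vs_ref=res.delta, z=res.z, p=res.p)
            rows.append(row)
    report = pd.DataFrame(rows)
    tested = report["p"].notna()
    report["q"] = np.nan
    report["reject"] = False
    if tested.any():
        q, reject = bh_adjust(report.loc[tested, "p"].to_numpy(), alpha=alpha)
        report.loc[tested, "q"] = q
        report.loc[tested, "reject"] = reject
    return report
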