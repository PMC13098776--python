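"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from first principles by a route
deliberately different from the library implementation (minute-by-minute
event loops, exhaustive pair enumeration, direct definitions), so
agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def minute_loop_alerts(grid_h, probs, events_h, threshold, refractory_h,
                       censor_h, strict=False):
    """Minute-resolution replay of the alert process for one admission.

    Walks every minute of the stay; at minutes that coincide with a grid
    point, checks the probability against the threshold and the explicit
    refractory / censor interval definitions.  Assumes grid times and
    event times are whole minutes.
    """
    grid_min = {int(round(t * 60)): p for t, p in zip(grid_h, probs)}
    events_min = sorted(int(round(e * 60)) for e in events_h)
    end_min = int(round(max(grid_h) * 60)) if len(grid_h) else -1
    alerts = []
    last_alert_min = None
    for m in range(end_min + 1):
        if m not in grid_min:
            continue
        p = grid_min[m]
        fire = p > threshold if strict else p >= threshold
        if not fire:
            continue
        if last_alert_min is not None:
            # refractory blocks the open interval (a, a + R)
            if last_alert_min < m < last_alert_min + refractory_h * 60:
                continue
        censored = any(e <= m < e + censor_h * 60 for e in events_min)
        if censored:
            continue
        alerts.append(m / 60.0)
        last_alert_min = m
    return np.asarray(alerts)


def pairwise_auroc(scores, labels):
    """AUROC by enumerating every positive-negative pair (ties half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def ladder_auprc(scores, labels):
    """Average precision from the precision/recall ladder over unique
    thresholds (prediction rule: score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for thr in np.sort(np.unique(scores))[::-1]:
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def stepup_bh(pvalues, alpha=0.05):
    """Benjamini-Hochberg directly from the definition.

    q_(i) = min_{j >= i} m * p_(j) / j (sorted ascending), capped at 1;
    reject H_(i) iff q_(i) < alpha is equivalent to the classic step-up
    rule at level alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    # step-up rejection: largest k with p_(k) <= k/m * alpha; reject 1..k
    reject = np.zeros(m, dtype=bool)
    ks = np.nonzero(p[order] <= np.arange(1, m + 1) / m * alpha)[0]
    if len(ks):
        reject[order[:ks[-1] + 1]] = True
    return q, reject


def jackknife_auroc_variance(scores, labels):
    """Leave-one-out jackknife variance of the AUROC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(scores)
    loo = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        loo[i] = pairwise_auroc(scores[mask], labels[mask])
    return (n - 1) / n * float(((loo - loo.mean()) ** 2).sum())
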