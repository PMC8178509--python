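"""Performance metrics for binary and survival predictions.

Covers ROC/AUC for binary outcomes, Harrell's concordance for risk scores
against censored survival, the IPCW (inverse probability of censoring
weighting) estimator of the cumulative/dynamic time-dependent ROC at a fixed
horizon, and a one-sided Wilcoxon rank-sum comparison of predicted risk
between relapsed and CCR patients.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = ["roc_auc", "concordance", "ipcw_td_roc", "rank_sum_test"]


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (Mann-Whitney probability, ties counted 1/2) and the ROC curve.

    Returns ``(auc, fpr, tpr)``; the curve starts at (0, 0) and ends at (1, 1).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute an ROC curve")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * equal) / (pos.size * neg.size)
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(auc), fpr, tpr


def concordance(risk, time, event) -> float:
    """Harrell's c: among usable pairs (the earlier time has an event), the
    fraction where the earlier-failing sample carries the higher risk; tied
    risks count 1/2."""
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    earlier = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_usable = earlier.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs: need an event preceding another observation")
    higher = (risk[:, None] > risk[None, :])[earlier].sum()
    tied = (risk[:, None] == risk[None, :])[earlier].sum()
    return float((higher + 0.5 * tied) / n_usable)


def _censoring_km(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier of the censoring distribution G(t)."""
    from sksurv.nonparametric import kaplan_meier_estimator

    censored = event == 0
    if not censored.any():
        return np.array([]), np.array([])
    t, s = kaplan_meier_estimator(censored, time)
    return np.asarray(t, float), np.asarray(s, float)


def _km_at(t_grid: np.ndarray, s_grid: np.ndarray, q: float, left: bool = False) -> float:
    """Right-continuous KM value G(q), or the left limit G(q-) when ``left``."""
    if t_grid.size == 0:
        return 1.0
    side = "left" if left else "right"
    idx = np.searchsorted(t_grid, q, side=side) - 1
    return 1.0 if idx < 0 else float(s_grid[idx])


def ipcw_td_roc(risk, time, event, horizon: float):
    """IPCW cumulative/dynamic time-dependent ROC at ``horizon``.

    Cases are subjects with an event at or before the horizon, weighted by
    1/G(T_i-); controls are subjects still event-free past the horizon,
    weighted by the common factor 1/G(horizon) (which cancels in the AUC).
    ``horizon`` is in the same time unit as ``time``.  Returns
    ``(auc, fpr, tpr)`` with the weighted empirical curve.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    if not cases.any():
        raise ValueError(f"no cases (events) at or before horizon {horizon}")
    if not controls.any():
        raise ValueError(f"no controls at risk beyond horizon {horizon}")

    tg, sg = _censoring_km(time, event)
    w = np.array([1.0 / max(_km_at(tg, sg, t, left=True), 1e-12) for t in time[cases]])
    r_case = risk[cases]
    r_ctrl = risk[controls]

    greater = (r_case[:, None] > r_ctrl[None, :]).sum(axis=1)
    equal = (r_case[:, None] == r_ctrl[None, :]).sum(axis=1)
    auc = float((w * (greater + 0.5 * equal)).sum() / (w.sum() * r_ctrl.size))

    thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([r_case, r_ctrl]))[::-1]))
    tpr = np.array([(w * (r_case >= c)).sum() / w.sum() for c in thresholds])
    fpr = np.array([(r_ctrl >= c).mean() for c in thresholds])
    return auc, fpr, tpr


def rank_sum_test(risk_relapsed, risk_ccr) -> float:
    """One-sided Wilcoxon rank-sum p-value for "relapsed risk > CCR risk".

    Uses exact enumeration for combined n <= 25 without ties, and the
    tie-corrected normal approximation otherwise.
    """
    x = np.asarray(risk_relapsed, float)
    y = np.asarray(risk_ccr, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 25 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue)
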