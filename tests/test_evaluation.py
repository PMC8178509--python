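"""Metrics: AUC, Harrell's c, IPCW time-dependent ROC and the rank-sum test.

Each metric is checked against an independent oracle: Mann-Whitney pair
enumeration for AUC, a double-loop pair count for concordance, a naive
direct-summation IPCW estimator, and full enumeration of rank assignments for
the exact rank-sum p-value.
"""

import itertools

import numpy as np
import pytest
from scipy import stats

from allsub import concordance, ipcw_td_roc, rank_sum_test, roc_auc


# ------------------------------------------------------------------ oracles

def mann_whitney_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_concordance(risk, time, event):
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den

def km_censoring(time, event):
    """Right-continuous Kaplan-Meier of the censoring distribution."""
    order = np.argsort(time)
    t_sorted, c_sorted = np.asarray(time)[order], (np.asarray(event)[order] == 0)
    at_risk = len(t_sorted)
    surv, ts, ss = 1.0, [], []
    for t in np.unique(t_sorted):
        here = t_sorted == t
        d = int((c_sorted & here).sum())
        if d:
            surv *= 1 - d / at_risk
            ts.append(t)
            ss.append(surv)
        at_risk -= int(here.sum())
    return np.array(ts), np.array(ss)


def direct_sum_ipcw_auc(risk, time, event, tau):
    ts, ss = km_censoring(time, event)

    def G_minus(t):
        s = 1.0
        for tk, sk in zip(ts, ss):
            if tk < t:
                s = sk
        return s

    num = wsum = 0.0
    n_ctrl = 0
    for j in range(len(risk)):
        if time[j] > tau:
            n_ctrl += 1
    for i in range(len(risk)):
        if time[i] <= tau and event[i] == 1:
            w = 1.0 / G_minus(time[i])
            wsum += w
            for j in range(len(risk)):
                if time[j] > tau:
                    num += w * (1.0 if risk[i] > risk[j]
                                else 0.5 if risk[i] == risk[j] else 0.0)
    return num / (wsum * n_ctrl)


# -------------------------------------------------------------------- tests

class TestRocAuc:
    def test_perfect_and_anti_perfect(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        assert roc_auc(scores, [1, 1, 0, 0])[0] == 1.0
        assert roc_auc(scores, [0, 0, 1, 1])[0] == 0.0

    def test_three_of_four_concordant_pairs(self):
        auc, _, _ = roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_mann_whitney_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 15)
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        auc, _, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a1, _, _ = roc_auc(scores, labels)
        a2, _, _ = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_curve_monotone_from_origin_to_one(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        _, fpr, tpr = roc_auc(scores, labels)
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestConcordance:
    def test_perfect_and_reversed(self):
        assert concordance([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0
        assert concordance([1, 2, 3], [1, 2, 3], [1, 1, 1]) == 0.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        risk = np.round(rng.normal(size=20), 1)
        time = np.round(rng.exponential(50, 20), 0) + 1
        event = rng.integers(0, 2, 20).astype(float)
        event[:2] = 1
        assert concordance(risk, time, event) == pytest.approx(
            brute_force_concordance(risk, time, event), abs=1e-12)

    def test_complementarity_without_ties(self, rng):
        risk = rng.normal(size=15)
        time = rng.exponential(10, 15)
        event = np.ones(15)
        assert concordance(risk, time, event) + concordance(-risk, time, event) \
            == pytest.approx(1.0, abs=1e-12)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            concordance([1.0, 2.0], [5.0, 5.0], [0.0, 0.0])


class TestIpcwTdRoc:
    def test_reduces_to_plain_auc_without_censoring(self, rng):
        n = 40
        risk = rng.normal(size=n)
        time = rng.exponential(100, n)
        event = np.ones(n)
        tau = float(np.median(time))
        auc_td, _, _ = ipcw_td_roc(risk, time, event, tau)
        auc_plain, _, _ = roc_auc(risk, (time <= tau).astype(int))
        assert auc_td == pytest.approx(auc_plain, abs=1e-12)

    def test_perfect_ranking_gives_one(self):
        risk = np.array([3.0, 2.5, 1.0, 0.5])
        time = np.array([10.0, 20.0, 100.0, 200.0])
        event = np.array([1.0, 1.0, 0.0, 0.0])
        auc, _, _ = ipcw_td_roc(risk, time, event, 50.0)
        assert auc == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        risk = rng.normal(size=n)
        t_ev = rng.exponential(100, n)
        cens = rng.exponential(250, n)  # roughly 30% censoring
        time = np.minimum(t_ev, cens)
        event = (t_ev <= cens).astype(float)
        tau = float(np.quantile(time, 0.5))
        if not ((time <= tau) & (event == 1)).any() or not (time > tau).any():
            pytest.skip("degenerate draw")
        auc, _, _ = ipcw_td_roc(risk, time, event, tau)
        assert auc == pytest.approx(direct_sum_ipcw_auc(risk, time, event, tau),
                                    abs=1e-10)

    def test_errors_name_the_horizon(self):
        with pytest.raises(ValueError, match="5.0"):
            ipcw_td_roc([1.0, 2.0], [10.0, 20.0], [1.0, 1.0], 5.0)


class TestRankSum:
    def test_exact_p_for_separated_groups(self):
        # all relapsed above all CCR: p = 1 / C(6,3) = 0.05
        assert rank_sum_test([5, 6, 7], [1, 2, 3]) == pytest.approx(0.05, abs=1e-12)

    def test_identical_groups_not_significant(self):
        p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.5

    def test_exact_matches_full_enumeration(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5)
        y = rng.normal(size=4)
        p = rank_sum_test(x, y)
        # enumerate all rank assignments of the combined sample
        combined = np.concatenate([x, y])
        ranks = stats.rankdata(combined)
        obs = ranks[:5].sum()
        total = better = 0
        for subset in itertools.combinations(range(9), 5):
            total += 1
            if ranks[list(subset)].sum() >= obs - 1e-12:
                better += 1
        assert p == pytest.approx(better / total, abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        # combined n = 26 exceeds the exact-enumeration cutoff, forcing the
        # tie-corrected normal approximation; compare with exact enumeration
        x = rng.normal(0.8, 1.0, 13)
        y = rng.normal(0.0, 1.0, 13)
        p_ours = rank_sum_test(x, y)
        p_exact = float(stats.mannwhitneyu(x, y, alternative="greater",
                                           method="exact").pvalue)
        assert p_ours == pytest.approx(p_exact, rel=0.10)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(0)
        pvals = [rank_sum_test(rng.normal(size=12), rng.normal(size=12))
                 for _ in range(2000)]
        stat = stats.kstest(pvals, "uniform").pvalue
        assert stat > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1.0])
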