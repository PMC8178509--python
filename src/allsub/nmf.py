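"""Multi-run NMF with KL multiplicative updates, consensus analysis and run averaging.

The factorization V ~= W.H (W m x r basis, H r x n coefficients, both
non-negative) is fitted by Lee-Seung multiplicative updates for the
generalized Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ],

whose objective is non-increasing under the updates.  Subgroup membership of
sample j is the argmax over column j of H.  Because a single run depends on
its random start, the standard routine performs many runs, ranks them by the
objective value, summarizes their agreement in a consensus matrix, and
(optionally) averages the factor matrices of the best runs after resolving
the scaling and permutation ambiguities of NMF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

_EPS = 1e-12

__all__ = [
    "FactorizationResult",
    "RunEnsemble",
    "SubgroupAssignment",
    "nmf_factorize",
    "nmf_multirun",
    "consensus_matrix",
    "average_top_runs",
    "assign_subgroups",
    "kl_divergence",
]


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH); the NMF objective."""
    mask = V > 0
    total = float(WH.sum() - V[mask].sum())
    total += float(np.sum(V[mask] * np.log(V[mask] / (WH[mask] + _EPS))))
    return total


@dataclass
class FactorizationResult:
    """A single NMF run: factors, rank, final objective value and diagnostics."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    error: float
    seed: int
    n_iter: int
    objective_history: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class RunEnsemble:
    """Runs of NMF on the same matrix at the same rank, sorted by ascending error."""

    V: np.ndarray
    rank: int
    runs: list[FactorizationResult]

    @property
    def best(self) -> FactorizationResult:
        return self.runs[0]


@dataclass
class SubgroupAssignment:
    """Per-sample subgroup labels (1..r) from the argmax over coefficient columns."""

    sample_ids: list[str]
    labels: np.ndarray
    coefficients: np.ndarray


def _validate_input(V: np.ndarray, rank: int) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    if (V < 0).any():
        raise ValueError("V must be non-negative for NMF")
    m, n = V.shape
    if not 1 <= rank <= min(m, n):
        raise ValueError(f"rank must satisfy 1 <= r <= min(m, n)={min(m, n)}, got {rank}")
    return V


def nmf_factorize(
    V: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FactorizationResult:
    """One NMF run with multiplicative KL updates from a random start.

    Initial entries of W and H are i.i.d. uniform on (0, 1] scaled by mean(V).
    Iteration stops when the relative objective change falls below ``tol`` or
    after ``max_iter`` iterations.
    """
    V = _validate_input(V, rank)
    m, n = V.shape
    rng = np.random.default_rng(seed)
    scale = max(V.mean(), _EPS)
    # uniform on (0, 1]: flip the half-open interval of random.uniform
    W = (1.0 - rng.random((m, rank))) * scale
    H = 1.0 - rng.random((rank, n))

    history = []
    prev = np.inf
    obj = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        obj = kl_divergence(V, W @ H)
        history.append(obj)
        if np.isfinite(prev) and abs(prev - obj) <= tol * max(abs(prev), 1.0):
            break
        prev = obj
    return FactorizationResult(
        W=W, H=H, rank=rank, error=obj, seed=seed, n_iter=it,
        objective_history=np.asarray(history),
    )


def nmf_multirun(
    V: np.ndarray,
    rank: int,
    n_runs: int = 30,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> RunEnsemble:
    """Repeated stochastic-seeding NMF; run k uses seed ``base_seed + k``.

    Runs are returned sorted by ascending objective value, so ``ensemble.best``
    is the lowest-error run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    V = _validate_input(V, rank)
    runs = [
        nmf_factorize(V, rank, seed=base_seed + k, max_iter=max_iter, tol=tol)
        for k in range(n_runs)
    ]
    runs.sort(key=lambda r: r.error)
    return RunEnsemble(V=V, rank=rank, runs=runs)


def consensus_matrix(ensemble: RunEnsemble) -> np.ndarray:
    """n x n matrix of the fraction of runs in which each sample pair co-clusters."""
    if not ensemble.runs:
        raise ValueError("ensemble contains no runs")
    n = ensemble.V.shape[1]
    C = np.zeros((n, n))
    for run in ensemble.runs:
        labels = np.argmax(run.H, axis=0)
        C += (labels[:, None] == labels[None, :]).astype(float)
    C /= len(ensemble.runs)
    return C


def _normalize_factors(
    W: np.ndarray, H: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale columns of W to unit sum with compensating row scaling of H."""
    s = W.sum(axis=0)
    s_safe = np.where(s > 0, s, 1.0)
    return W / s_safe, H * s_safe[:, None], s_safe


def _align_to(W_ref: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Permutation p maximizing total cosine similarity of W[:, p] with W_ref columns."""
    norm_ref = np.linalg.norm(W_ref, axis=0) + _EPS
    norm = np.linalg.norm(W, axis=0) + _EPS
    sim = (W_ref.T @ W) / np.outer(norm_ref, norm)
    row_ind, col_ind = linear_sum_assignment(-sim)
    perm = np.empty_like(col_ind)
    perm[row_ind] = col_ind
    return perm


def average_top_runs(ensemble: RunEnsemble, top_k: int) -> FactorizationResult:
    """Average W and H over the ``top_k`` lowest-error runs.

    Each selected run is first scale-normalized (unit-sum W columns, with
    compensating row scaling of H) and then permutation-aligned to the best
    run by maximal total cosine similarity of basis columns (optimal
    one-to-one assignment).  The normalized factors are averaged entrywise and
    the averaged components are rescaled by the mean of the aligned scale
    vectors, so that averaging k copies of one run returns that run exactly.
    The objective is recomputed on the averaged factors.
    """
    if top_k < 1:
        raise ValueError("top_k must be at least 1")
    if top_k > len(ensemble.runs):
        raise ValueError(f"top_k={top_k} exceeds number of runs ({len(ensemble.runs)})")
    best = ensemble.runs[0]
    W_ref, H_ref, s_ref = _normalize_factors(best.W, best.H)
    Ws, Hs, scales = [W_ref], [H_ref], [s_ref]
    for run in ensemble.runs[1:top_k]:
        Wn, Hn, sn = _normalize_factors(run.W, run.H)
        perm = _align_to(W_ref, Wn)
        Ws.append(Wn[:, perm])
        Hs.append(Hn[perm, :])
        scales.append(sn[perm])
    s_mean = np.mean(scales, axis=0)
    W_avg = np.mean(Ws, axis=0) * s_mean
    H_avg = np.mean(Hs, axis=0) / s_mean[:, None]
    return FactorizationResult(
        W=W_avg,
        H=H_avg,
        rank=ensemble.rank,
        error=kl_divergence(ensemble.V, W_avg @ H_avg),
        seed=best.seed,
        n_iter=best.n_iter,
    )


def assign_subgroups(H: np.ndarray, sample_ids: Sequence[str]) -> SubgroupAssignment:
    """Label sample j with the subgroup of the largest coefficient in column j.

    Labels are 1-based.  Ties break to the lowest component index; an all-zero
    column falls back to subgroup 1 with a warning.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("H must be a 2-D matrix with at least one row")
    if H.shape[1] != len(sample_ids):
        raise ValueError("number of sample ids must match columns of H")
    zero_cols = np.where(~H.any(axis=0))[0]
    if zero_cols.size:
        warnings.warn(
            f"{zero_cols.size} all-zero coefficient column(s); assigned to subgroup 1 "
            f"by the tie-break rule", stacklevel=2)
    labels = np.argmax(H, axis=0) + 1
    return SubgroupAssignment(list(map(str, sample_ids)), labels, H)
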