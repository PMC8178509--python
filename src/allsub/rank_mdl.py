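"""Minimum-description-length rank selection for NMF.

The description length of a factorization V ~= W.H is the number of bits
needed to transmit W, H and the residual V - W.H, each quantized to a finite
precision and coded with Shannon lengths -log2(p).  Two codings are provided:

* ``histogram`` - p comes from the empirical histogram of the quantized
  values of the matrix being coded (plus the cost of transmitting the
  occupied bins and their counts);
* ``fitted`` - p is the probability mass a fitted parametric density assigns
  to the value's quantization bin (exponential for the non-negative factor
  entries; gene-wise Gaussians for the residual, since expression noise is
  heteroscedastic across genes), plus (k/2) log2(N) bits for the k fitted
  parameters.

Because the entries of W and H are parameters of the model for V rather than
data, each additionally carries the standard (1/2) log2(|V|) parametric
complexity on top of its quantized-value code.  Increasing the rank shrinks
the residual code but grows the factor code; the selected rank minimizes the
total.  W and H are quantized over their own value range; the residual is
quantized with a step derived from the range of V itself, so that a residual
which genuinely shrinks with rank is rewarded with a shorter code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nmf import nmf_multirun

__all__ = ["DescriptionLength", "RankSelection", "description_length", "select_rank"]

_N_BINS = 512
_HEADER_BITS = 64.0  # fixed cost for transmitting offset and step of a matrix
_TINY = 1e-300


@dataclass
class DescriptionLength:
    """Total code length in bits for one factorization, under both codings."""

    rank: int
    bits_histogram: float
    bits_fitted: float
    components: dict

    def total(self, method: str) -> float:
        if method == "histogram":
            return self.bits_histogram
        if method == "fitted":
            return self.bits_fitted
        raise ValueError(f"unknown coding method {method!r}")


@dataclass
class RankSelection:
    """Result of an MDL sweep over candidate ranks."""

    selected_rank: int
    method: str
    table: list[DescriptionLength]

    def argmin(self, method: str) -> int:
        return min(self.table, key=lambda d: d.total(method)).rank


def _quantize(M: np.ndarray, step: float, lo: float) -> np.ndarray:
    idx = np.floor((M.ravel() - lo) / step).astype(np.int64)
    return np.clip(idx, 0, _N_BINS - 1)



def _histogram_bits(M: np.ndarray, step: float, lo: float) -> float:
    """Empirical-histogram Shannon code length plus histogram transmission cost."""
    x = M.ravel()
    N = x.size
    if step <= 0:
        return _HEADER_BITS  # constant matrix: nothing beyond the header
    counts = np.bincount(_quantize(M, step, lo), minlength=_N_BINS)
    nz = counts[counts > 0]
    data_bits = float(np.sum(nz * (np.log2(N) - np.log2(nz))))
    # each occupied bin: its index (log2 B bits) and its count (log2 N bits)
    model_bits = nz.size * (np.log2(_N_BINS) + np.log2(max(N, 2))) + _HEADER_BITS
    return data_bits + model_bits


def _fitted_bits(M: np.ndarray, step: float, family: str) -> float:
    """Code length under a fitted density, quantized to ``step``.

    Each value is coded with the probability mass the fitted distribution
    assigns to its quantization bin (CDF difference across the bin edges), so
    the per-element cost saturates at zero once the distribution concentrates
    inside a single bin.  Fitted parameters cost (k/2) log2(N) bits.
    """
    from scipy import stats as _st

    x = M.ravel()
    N = x.size
    if step <= 0:
        return _HEADER_BITS
    if family == "exponential":
        mean = x.mean()
        if mean <= 0:
            return _HEADER_BITS
        dist, k = _st.expon(scale=mean), 1
    elif family == "gaussian":
        # gene-wise Gaussians: expression noise is heteroscedastic across genes,
        # so the residual is modelled with one mean/sd per row of the matrix
        bits = 0.0
        n_cols = M.shape[1]
        for row in M:
            sd = row.std()
            if sd <= 0:
                continue
            dist = _st.norm(loc=row.mean(), scale=sd)
            lo = np.floor(row / step) * step
            p = np.clip(dist.cdf(lo + step) - dist.cdf(lo), _TINY, 1.0)
            bits += float(-np.sum(np.log2(p)))
        return bits + M.shape[0] * np.log2(max(n_cols, 2)) + _HEADER_BITS
    else:
        raise ValueError(f"unknown density family {family!r}")
    lo = np.floor(x / step) * step  # bin edges on a grid anchored at zero
    p = np.clip(dist.cdf(lo + step) - dist.cdf(lo), _TINY, 1.0)
    data_bits = float(-np.sum(np.log2(p)))
    return data_bits + 0.5 * k * np.log2(max(N, 2)) + _HEADER_BITS


def _step(M: np.ndarray) -> tuple[float, float]:
    lo, hi = float(M.min()), float(M.max())
    return (hi - lo) / _N_BINS, lo


def description_length(
    V: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    method: str = "histogram",
    precision: float | None = None,
) -> DescriptionLength:
    """Description length (bits) of V coded as W, H and the residual V - W.H.

    ``precision`` overrides the quantization step used for every matrix; by
    default W and H use (max-min)/512 of their own values and the residual
    uses (max(V)-min(V))/512.
    """
    V = np.asarray(V, float)
    W = np.asarray(W, float)
    H = np.asarray(H, float)
    if W.shape[0] != V.shape[0] or H.shape[1] != V.shape[1] or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"non-conforming shapes: V {V.shape}, W {W.shape}, H {H.shape}")
    if precision is not None and precision <= 0:
        raise ValueError("precision must be positive")
    step_v = (float(V.max()) - float(V.min())) / _N_BINS
    step_w, lo_w = _step(W)
    step_h, lo_h = _step(H)
    if precision is not None:
        step_w = step_h = step_v = precision
    R = V - W @ H

    # every factor entry is a parameter of the model for V, so beyond its
    # quantized-value code it carries the standard (1/2) log2(N) parametric
    # complexity, N being the number of data values the model describes
    param_bits = 0.5 * np.log2(max(V.size, 2))

    parts_hist = {}
    parts_fit = {}
    for name, M, family, step, lo in (
        ("W", W, "exponential", step_w, lo_w),
        ("H", H, "exponential", step_h, lo_h),
        ("residual", R, "gaussian", step_v, float(R.min())),
    ):
        extra = param_bits * M.size if name in ("W", "H") else 0.0
        parts_hist[name] = _histogram_bits(M, step, lo) + extra
        parts_fit[name] = _fitted_bits(M, step, family) + extra
    return DescriptionLength(
        rank=W.shape[1],
        bits_histogram=sum(parts_hist.values()),
        bits_fitted=sum(parts_fit.values()),
        components={"histogram": parts_hist, "fitted": parts_fit},
    )


def select_rank(
    V: np.ndarray,
    ranks: Sequence[int],
    runs_per_rank: int = 30,
    method: str = "histogram",
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    precision: float | None = None,
) -> RankSelection:
    """Factorize V at every candidate rank and return the MDL-minimizing rank.

    For each rank the best of ``runs_per_rank`` stochastic runs is coded; both
    coding methods are tabulated, and ``method`` decides which one drives the
    returned ``selected_rank``.  Deterministic given ``seed``.
    """
    ranks = list(ranks)
    if not ranks:
        raise ValueError("ranks must be non-empty")
    if method not in ("histogram", "fitted"):
        raise ValueError(f"unknown coding method {method!r}")
    table = []
    for r in ranks:
        base = (seed * 1009 + r * 7919) % (2**31)
        best = nmf_multirun(V, r, n_runs=runs_per_rank, base_seed=base,
                            max_iter=max_iter, tol=tol).best
        table.append(description_length(V, best.W, best.H, precision=precision))
    selected = min(table, key=lambda d: d.total(method)).rank
    return RankSelection(selected_rank=selected, method=method, table=table)
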