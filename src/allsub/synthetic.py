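"""Synthetic cohort generator with the statistical structure the pipeline assumes.

Expression is a low-rank non-negative product W_true . H_true (gamma-distributed
factor entries; signature genes load high in their own subgroup's basis column)
under multiplicative lognormal noise, so the matrix is non-negative by
construction and exactly rank-r when the noise is switched off.  Each subgroup
carries a sparse outcome signature: a logistic model on standardized signature
genes drives the binary early-response outcome, and an exponential
proportional-hazards model with subgroup-specific baseline rates drives
relapse-free survival, censored by an independent uniform time calibrated to a
target censoring fraction.  A paired training/test study shares the true basis
and outcome coefficients so that projection and model transfer can be tested
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .data_io import ExpressionMatrix, OutcomeTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "SyntheticStudy",
    "generate_cohorts",
    "generate_rank_series",
]

_GAMMA_SHAPE = 4.0  # shape of factor-entry distributions (CV = 1/2)
_DAYS_PER_YEAR = 365.25
# baseline median RFS per subgroup, years (cycled when r > 4)
_BASELINE_MEDIANS = (4.0, 5.0, 6.0, 7.0)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the cohort shapes the pipeline targets."""

    m: int = 370
    n_train: int = 200
    n_test: int = 100
    r: int = 4
    signature_size: int = 30
    basis_high: float = 50.0
    basis_low: float = 2.0
    coef_high: float = 1.0
    coef_low: float = 0.05
    noise_cv: float = 0.2
    outcome_genes: int = 5
    logit_effect: float = 1.0
    base_prevalence: float = 0.35
    hazard_effect: float = 0.7
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r < 2:
            raise ValueError("need at least 2 subgroups")
        if self.signature_size * self.r > self.m:
            raise ValueError(
                f"signature_size * r = {self.signature_size * self.r} exceeds m = {self.m}")
        if self.outcome_genes > self.signature_size:
            raise ValueError("outcome_genes cannot exceed signature_size")
        for name in ("m", "n_train", "n_test", "signature_size", "outcome_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("basis_high", "basis_low", "coef_high", "coef_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0 < self.base_prevalence < 1:
            raise ValueError("base_prevalence must be in (0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth for one cohort: labels, factors and outcome coefficients."""

    labels: np.ndarray  # 1..r per sample
    W_true: np.ndarray
    H_true: np.ndarray
    signature_genes: list[list[int]]  # gene indices per subgroup
    outcome_gene_idx: list[np.ndarray]  # per subgroup, indices of predictive genes
    logistic_coefs: list[np.ndarray]  # per subgroup, per-gene log-odds effects
    cox_coefs: list[np.ndarray]  # per subgroup, per-gene log-hazard effects
    event_time_true: np.ndarray | None = None  # pre-censoring event times (days)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    outcomes: OutcomeTable
    truth: SyntheticTruth


@dataclass
class SyntheticStudy:
    """A paired training/test study sharing W_true and outcome coefficients."""

    train: SyntheticCohort
    test: SyntheticCohort
    config: SyntheticConfig


def _draw_labels(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    # near-balanced subgroups in random order; every subgroup non-empty for n >= r
    return rng.permutation(np.arange(n) % r) + 1


def _zscore_within(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / np.where(sd > 0, sd, 1.0)


def _calibrate_uniform_censoring(rng, t_event: np.ndarray, target: float) -> np.ndarray:
    """Uniform(0, c) censoring times with c chosen so that P(C < T) ~= target."""
    if target <= 0:
        return np.full_like(t_event, np.inf)

    def frac_censored(c):
        return np.minimum(t_event / c, 1.0).mean()

    lo, hi = t_event.min() * 1e-3 + 1e-9, t_event.max() * 1e4
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac_censored(mid) > target:
            lo = mid
        else:
            hi = mid
    return rng.uniform(0.0, np.sqrt(lo * hi), size=t_event.size)


def _make_cohort(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    n: int,
    prefix: str,
    W_true: np.ndarray,
    signatures: list[list[int]],
    outcome_idx: list[np.ndarray],
    beta_log: list[np.ndarray],
    gamma_cox: list[np.ndarray],
    with_longterm: bool,
) -> SyntheticCohort:
    labels = _draw_labels(rng, n, cfg.r)

    H = rng.gamma(_GAMMA_SHAPE, cfg.coef_low / _GAMMA_SHAPE, size=(cfg.r, n))
    for g in range(cfg.r):
        own = labels == g + 1
        H[g, own] = rng.gamma(_GAMMA_SHAPE, cfg.coef_high / _GAMMA_SHAPE, size=own.sum())

    V = W_true @ H
    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
        V = V * rng.lognormal(-sigma**2 / 2.0, sigma, size=V.shape)

    gene_ids = [f"G{i:04d}" for i in range(cfg.m)]
    sample_ids = [f"{prefix}{j:04d}" for j in range(n)]
    expr = ExpressionMatrix(gene_ids, sample_ids, V)

    # outcomes on expression standardized within each subgroup
    y = np.zeros(n)
    t_event = np.zeros(n)
    for g in range(cfg.r):
        own = np.where(labels == g + 1)[0]
        Z = _zscore_within(V[np.ix_(outcome_idx[g], own)])
        lp_logit = logit(cfg.base_prevalence) + beta_log[g] @ Z
        y[own] = rng.binomial(1, expit(lp_logit))
        lp_cox = gamma_cox[g] @ Z
        median_y = _BASELINE_MEDIANS[g % len(_BASELINE_MEDIANS)]
        rate = np.log(2.0) / (median_y * _DAYS_PER_YEAR)
        t_event[own] = rng.exponential(1.0 / (rate * np.exp(lp_cox)))

    c = _calibrate_uniform_censoring(rng, t_event, cfg.censor_rate)
    event = (t_event <= c).astype(float)
    obs_time = np.minimum(t_event, c)
    obs_time = np.maximum(obs_time, 1.0)  # at least one day of follow-up

    early = np.where(y == 1, "bad", "good").astype(object)
    longterm = None
    if with_longterm:
        longterm = np.full(n, None, dtype=object)
        longterm[(event == 1) & (obs_time <= 3 * _DAYS_PER_YEAR)] = "relapsed"
        longterm[obs_time > 4 * _DAYS_PER_YEAR] = "CCR"

    outcomes = OutcomeTable(
        sample_ids,
        early_response=early,
        rfs_time=obs_time,
        rfs_event=event,
        longterm_class=longterm,
    )
    truth = SyntheticTruth(
        labels=labels, W_true=W_true, H_true=H, signature_genes=signatures,
        outcome_gene_idx=outcome_idx, logistic_coefs=beta_log, cox_coefs=gamma_cox,
        event_time_true=t_event,
    )
    return SyntheticCohort(expression=expr, outcomes=outcomes, truth=truth)


def generate_cohorts(cfg: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate a paired training/test study from one config; deterministic given cfg.seed."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # disjoint signature blocks, one per subgroup
    perm = rng.permutation(cfg.m)
    signatures = [
        sorted(perm[g * cfg.signature_size:(g + 1) * cfg.signature_size].tolist())
        for g in range(cfg.r)
    ]
    W = rng.gamma(_GAMMA_SHAPE, cfg.basis_low / _GAMMA_SHAPE, size=(cfg.m, cfg.r))
    for g, sig in enumerate(signatures):
        W[sig, g] = rng.gamma(_GAMMA_SHAPE, cfg.basis_high / _GAMMA_SHAPE, size=len(sig))

    # effects share one sign per subgroup: within a subgroup the signature
    # genes are strongly correlated (they track the same basis component), so
    # mixed signs would cancel and leave the outcome mostly noise-driven
    outcome_idx = [np.array(sig[: cfg.outcome_genes]) for sig in signatures]
    beta_log = [np.full(cfg.outcome_genes, cfg.logit_effect) for _ in range(cfg.r)]
    gamma_cox = [np.full(cfg.outcome_genes, cfg.hazard_effect) for _ in range(cfg.r)]

    train = _make_cohort(cfg, rng, cfg.n_train, "TR", W, signatures, outcome_idx,
                         beta_log, gamma_cox, with_longterm=False)
    test = _make_cohort(cfg, rng, cfg.n_test, "TS", W, signatures, outcome_idx,
                        beta_log, gamma_cox, with_longterm=True)
    return SyntheticStudy(train=train, test=test, config=cfg)


def generate_rank_series(
    cfg: SyntheticConfig | None = None, true_ranks: Sequence[int] = (2, 4, 6),
) -> list[SyntheticStudy]:
    """One study per requested true rank, with seeds drawn from a shared stream."""
    cfg = cfg or SyntheticConfig()
    if not true_ranks:
        raise ValueError("true_ranks must be non-empty")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(true_ranks))
    studies = []
    for r, child in zip(true_ranks, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        studies.append(generate_cohorts(replace(cfg, r=r, seed=child_seed)))
    return studies
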