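"""Expression matrices, outcome tables, gene filtering and cross-cohort intersection.

Expression is stored genes x samples on the linear scale (no log transform is
applied anywhere in the pipeline).  Outcome tables carry a binary early-response
status (good/bad), relapse-free survival in days with an event flag, and/or a
long-term class (CCR/relapsed); any of the three may be missing per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "OutcomeTable",
    "GeneFilterConfig",
    "read_expression",
    "write_expression",
    "read_outcomes",
    "write_outcomes",
    "filter_genes",
    "intersect_gene_sets",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """A non-negative genes x samples expression matrix with identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("expression matrix must have at least one gene and one sample")
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if np.isnan(self.values).any():
            i, j = np.argwhere(np.isnan(self.values))[0]
            raise ValueError(
                f"missing value at gene {self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``gene_ids``, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows, :])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not present in matrix: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])


# tri-state outcome codes used in CSV files
_MISSING = {"", "na", "nan", "none", None}


@dataclass
class OutcomeTable:
    """Per-sample clinical outcomes aligned with an expression matrix.

    ``early_response`` holds "good"/"bad"/None; ``longterm_class`` holds
    "CCR"/"relapsed"/None.  ``rfs_time`` is in days, ``rfs_event`` is 1 for
    relapse and 0 for censoring; both are NaN where unavailable and must be
    present or absent together per sample.
    """

    sample_ids: list[str]
    early_response: np.ndarray | None = None
    rfs_time: np.ndarray | None = None
    rfs_event: np.ndarray | None = None
    longterm_class: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        if (self.rfs_time is None) != (self.rfs_event is None):
            raise ValueError("rfs_time and rfs_event must be given together")
        if self.early_response is None and self.rfs_time is None and self.longterm_class is None:
            raise ValueError("at least one outcome column is required")
        for name in ("early_response", "longterm_class"):
            col = getattr(self, name)
            if col is not None:
                col = np.asarray(
                    [None if (isinstance(v, float) and np.isnan(v)) or
                     (isinstance(v, str) and v.strip().lower() in _MISSING) or v is None
                     else str(v) for v in col], dtype=object)
                if len(col) != n:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, col)
        if self.early_response is not None:
            bad = {v for v in self.early_response if v not in (None, "good", "bad")}
            if bad:
                raise ValueError(f"early_response values must be good/bad/NA, got {sorted(bad)}")
        if self.longterm_class is not None:
            bad = {v for v in self.longterm_class if v not in (None, "CCR", "relapsed")}
            if bad:
                raise ValueError(f"longterm_class values must be CCR/relapsed/NA, got {sorted(bad)}")
        if self.rfs_time is not None:
            self.rfs_time = np.asarray(self.rfs_time, dtype=float)
            self.rfs_event = np.asarray(self.rfs_event, dtype=float)
            if len(self.rfs_time) != n or len(self.rfs_event) != n:
                raise ValueError("rfs column length mismatch")
            finite = self.rfs_time[np.isfinite(self.rfs_time)]
            if finite.size and finite.min() < 0:
                raise ValueError("rfs_time must be non-negative")
            if (np.isnan(self.rfs_time) != np.isnan(self.rfs_event)).any():
                raise ValueError("rfs_time and rfs_event must be missing together")
            observed = self.rfs_event[~np.isnan(self.rfs_event)]
            if not np.isin(observed, (0.0, 1.0)).all():
                raise ValueError("rfs_event must be 0 (censored) or 1 (relapse)")

    def subset(self, sample_ids: Sequence[str]) -> "OutcomeTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not present in outcomes: {missing[:5]}")
        rows = np.array([index[s] for s in sample_ids])

        def take(col):
            return None if col is None else col[rows]

        return OutcomeTable(
            list(sample_ids),
            early_response=take(self.early_response),
            rfs_time=take(self.rfs_time),
            rfs_event=take(self.rfs_event),
            longterm_class=take(self.longterm_class),
        )


@dataclass
class GeneFilterConfig:
    """Background/variability gene filter.

    A gene is kept when its expression exceeds ``background_threshold`` in
    strictly more than ``min_fraction`` of samples AND its coefficient of
    variation (sample sd / mean) strictly exceeds ``cov_min``.
    """

    background_threshold: float = 100.0
    min_fraction: float = 0.10
    cov_min: float = 1.0

    def __post_init__(self) -> None:
        if self.background_threshold <= 0:
            raise ValueError("background_threshold must be positive")
        if not 0 < self.min_fraction < 1:
            raise ValueError("min_fraction must be in (0, 1)")
        if self.cov_min < 0:
            raise ValueError("cov_min must be non-negative")


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    return "\t" if fmt == "tsv" else ","


def read_expression(path: str | Path, fmt: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression table (first column gene ids, header sample ids)."""
    path = Path(path)
    sep = _sep_for(path, fmt)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # numpy's parser is correctly rounded (pandas' fast path is not)
            values[:, j] = df[col].to_numpy(dtype="U32").astype(float)
        except ValueError:
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: malformed numeric value {cell!r} at "
                        f"gene {df.index[i]!r}, sample {col!r}") from None
            raise
    return ExpressionMatrix(df.index.tolist(), [str(c) for c in df.columns], values)


def write_expression(expr: ExpressionMatrix, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, fmt)
    # %.17g round-trips IEEE doubles exactly
    expr.to_dataframe().to_csv(path, sep=sep, index_label="gene_id", float_format="%.17g")


def read_outcomes(path: str | Path) -> OutcomeTable:
    """Read an outcome CSV with columns sample_id, early_response, rfs_time_days, rfs_event, longterm_class."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    kw = {}
    if "early_response" in df.columns:
        kw["early_response"] = df["early_response"].to_numpy(dtype=object)
    if "rfs_time_days" in df.columns:
        kw["rfs_time"] = df["rfs_time_days"].to_numpy(dtype=float)
        kw["rfs_event"] = df["rfs_event"].to_numpy(dtype=float)
    if "longterm_class" in df.columns:
        kw["longterm_class"] = df["longterm_class"].to_numpy(dtype=object)
    return OutcomeTable(df["sample_id"].tolist(), **kw)


def write_outcomes(table: OutcomeTable, path: str | Path) -> None:
    data = {"sample_id": table.sample_ids}
    if table.early_response is not None:
        data["early_response"] = ["NA" if v is None else v for v in table.early_response]
    if table.rfs_time is not None:
        data["rfs_time_days"] = table.rfs_time
        data["rfs_event"] = table.rfs_event
    if table.longterm_class is not None:
        data["longterm_class"] = ["NA" if v is None else v for v in table.longterm_class]
    pd.DataFrame(data).to_csv(path, index=False)


def filter_genes(expr: ExpressionMatrix, cfg: GeneFilterConfig | None = None) -> list[str]:
    """Gene ids passing the background-presence and coefficient-of-variation filter.

    Both inequalities are strict.  Genes with zero mean have an undefined COV
    and are excluded (they trivially fail the background criterion as well).
    Input order is preserved.
    """
    cfg = cfg or GeneFilterConfig()
    V = expr.values
    n = expr.n_samples
    above = (V > cfg.background_threshold).sum(axis=1) / n > cfg.min_fraction
    mean = V.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = V.std(axis=1, ddof=1) if n > 1 else np.zeros(expr.n_genes)
        cov = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    variable = np.where(np.isnan(cov), False, cov > cfg.cov_min)
    keep = above & variable
    return [g for g, k in zip(expr.gene_ids, keep) if k]


def intersect_gene_sets(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Set intersection of two gene lists, ordered as in ``a``."""
    b_set = set(b)
    seen: set[str] = set()
    out = []
    for g in a:
        if g in b_set and g not in seen:
            seen.add(g)
            out.append(g)
    return out
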