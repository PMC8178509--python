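"""Projection of an external cohort onto a learned NMF basis.

Given the basis W learned on the training cohort, coefficients for a test
cohort V' are obtained as H' = W+ . V', where W+ = T D+ S^T is the
Moore-Penrose pseudoinverse from the SVD W = S D T^T.  H' is the unconstrained
least-squares solution and may contain negative entries; subgroup assignment
applies the same argmax rule as in training, directly on the signed
coefficients.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data_io import ExpressionMatrix
from .nmf import SubgroupAssignment

__all__ = ["pseudoinverse", "project_cohort", "assign_projected", "align_genes"]


def pseudoinverse(W: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Moore-Penrose pseudoinverse via SVD.

    Reciprocals are taken only for singular values above ``rcond`` times the
    largest singular value.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("W must be a 2-D matrix")
    S, d, Tt = np.linalg.svd(W, full_matrices=False)
    if d.size == 0 or d[0] <= 0:
        raise ValueError("cannot invert an all-zero matrix")
    d_inv = np.where(d > rcond * d[0], 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return (Tt.T * d_inv) @ S.T


def align_genes(basis_gene_ids: Sequence[str], expr: ExpressionMatrix) -> np.ndarray:
    """Rows of ``expr`` reordered to the basis gene order; error on missing genes."""
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in basis_gene_ids if g not in index]
    if missing:
        raise ValueError(
            f"{len(missing)} basis gene(s) missing from the cohort, e.g. {missing[:5]}")
    rows = [index[g] for g in basis_gene_ids]
    return expr.values[rows, :]


def project_cohort(W: np.ndarray, V_prime: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Coefficients H' = W+ . V' for a cohort whose rows are aligned to W's genes.

    Each column of the result is the least-squares minimizer of
    ||v'_j - W h||; negative entries are permitted and passed through.
    """
    W = np.asarray(W, dtype=float)
    V_prime = np.asarray(V_prime, dtype=float)
    if V_prime.ndim != 2 or V_prime.shape[0] != W.shape[0]:
        raise ValueError(
            f"gene dimension mismatch: basis has {W.shape[0]} rows, "
            f"cohort has {V_prime.shape[0] if V_prime.ndim == 2 else '?'}")
    return pseudoinverse(W, rcond=rcond) @ V_prime


def assign_projected(H_prime: np.ndarray, sample_ids: Sequence[str]) -> SubgroupAssignment:
    """Argmax subgroup labels over (possibly negative) projected coefficients.

    Ties break to the lowest component index, as in training.
    """
    H_prime = np.asarray(H_prime, dtype=float)
    if H_prime.ndim != 2 or H_prime.shape[0] < 1:
        raise ValueError("H' must be a 2-D matrix with at least one row")
    if H_prime.shape[1] != len(sample_ids):
        raise ValueError("number of sample ids must match columns of H'")
    labels = np.argmax(H_prime, axis=0) + 1
    return SubgroupAssignment(list(map(str, sample_ids)), labels, H_prime)
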