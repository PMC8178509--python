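#!/usr/bin/env python
"""Factorize the training cohort and assign expression subgroups.

Runs 60 stochastic NMF runs at the selected rank, averages the W and H
matrices over the 20 lowest-error runs (after scale normalization and
permutation alignment), assigns each sample to the subgroup with the largest
coefficient, and writes the factors, the 30-run consensus matrix and the
assignments.  A consensus heatmap is rendered when matplotlib is available.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from allsub import (
    assign_subgroups,
    average_top_runs,
    consensus_matrix,
    nmf_multirun,
    read_expression,
)

DATA = Path("results/data")
TABLES = Path("results/tables")
SEED = 505


def main() -> None:
    shared = json.loads((TABLES / "gene_filter.json").read_text())["genes"]
    rank = json.loads((TABLES / "selected_rank.json").read_text())["histogram"]
    train = read_expression(DATA / "train_expression.tsv").subset_genes(shared)

    ensemble = nmf_multirun(train.values, rank, n_runs=60, base_seed=SEED,
                            max_iter=400, tol=1e-5)
    averaged = average_top_runs(ensemble, top_k=20)
    assign = assign_subgroups(averaged.H, train.sample_ids)

    comp = [f"C{i+1}" for i in range(rank)]
    pd.DataFrame(averaged.W, index=train.gene_ids, columns=comp).to_csv(
        TABLES / "basis_W.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(averaged.H, index=comp, columns=train.sample_ids).to_csv(
        TABLES / "coefficients_H.tsv", sep="\t", index_label="component")
    pd.DataFrame({"sample_id": assign.sample_ids, "subgroup": assign.labels}).to_csv(
        TABLES / "train_subgroups.csv", index=False)

    C = consensus_matrix(ensemble)
    order = np.argsort(assign.labels, kind="stable")
    np.savetxt(TABLES / "consensus.tsv", C, delimiter="\t", fmt="%.4f")
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(C[np.ix_(order, order)], cmap="RdBu_r", vmin=0, vmax=1)
        ax.set_title(f"Consensus over {len(ensemble.runs)} runs (rank {rank})")
        fig.savefig(TABLES / "consensus.png", dpi=120)
    except ImportError:
        pass

    sizes = {g: int((assign.labels == g).sum()) for g in range(1, rank + 1)}
    print(f"rank {rank}; averaged best 20 of 60 runs "
          f"(best error {ensemble.best.error:.1f})")
    print("train subgroup sizes:", sizes)


if __name__ == "__main__":
    main()
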