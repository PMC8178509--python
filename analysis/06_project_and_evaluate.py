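#!/usr/bin/env python
"""Project the test cohort onto the learned basis and evaluate the models.

The test matrix is projected as H' = W+ . V' (Moore-Penrose pseudoinverse of
the averaged training basis) and each sample is assigned to the subgroup with
the largest projected coefficient.  Within each test subgroup, the training
MRD model is scored against the early-response labels (AUC) and the training
RFS model's risk scores are compared between relapsed and CCR patients with a
one-sided Wilcoxon rank-sum test.  Results go to results/report.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from allsub import (
    align_genes,
    assign_projected,
    predict_logistic,
    predict_risk,
    project_cohort,
    rank_sum_test,
    read_expression,
    read_outcomes,
    roc_auc,
)
from allsub.enet import FittedModel

DATA = Path("results/data")
TABLES = Path("results/tables")
MODELS = Path("results/models")


def _load_model(stem: Path) -> FittedModel:
    meta = json.loads(stem.with_suffix(".json").read_text())
    coef = pd.read_csv(stem.with_suffix(".csv"))
    return FittedModel(
        model_family=meta["family"], gene_ids=coef["gene_id"].tolist(),
        beta=coef["coefficient"].to_numpy(), lambda_used=meta["lambda"],
        k=meta["k"], intercept=meta["intercept"], subgroup=meta["subgroup"],
        degenerate=meta["degenerate"])


def main() -> None:
    shared = json.loads((TABLES / "gene_filter.json").read_text())["genes"]
    W = pd.read_csv(TABLES / "basis_W.tsv", sep="\t", index_col=0).to_numpy()
    test = read_expression(DATA / "test_expression.tsv")
    outcomes = read_outcomes(DATA / "test_outcomes.csv")

    H_prime = project_cohort(W, align_genes(shared, test))
    assign = assign_projected(H_prime, test.sample_ids)
    pd.DataFrame({"sample_id": assign.sample_ids, "subgroup": assign.labels}).to_csv(
        TABLES / "test_subgroups.csv", index=False)

    report = {"test_subgroup_sizes": {
        int(g): int((assign.labels == g).sum()) for g in np.unique(assign.labels)}}
    test_sub = test.subset_genes(shared)
    for g in sorted(set(assign.labels)):
        idx = np.where(assign.labels == g)[0]
        ids = [test.sample_ids[i] for i in idx]
        expr_g = test_sub.subset_samples(ids)
        out_g = outcomes.subset(ids)
        entry = {"n": len(ids)}

        mrd_stem = MODELS / f"subgroup{g}_mrd"
        if mrd_stem.with_suffix(".json").exists():
            model = _load_model(mrd_stem)
            keep = np.array([v is not None for v in out_g.early_response])
            y = np.array([1.0 if v == "bad" else 0.0
                          for v in out_g.early_response[keep]])
            if np.unique(y).size == 2:
                prob = predict_logistic(model, expr_g)[keep]
                entry["mrd_auc"] = round(roc_auc(prob, y)[0], 3)

        rfs_stem = MODELS / f"subgroup{g}_rfs"
        if rfs_stem.with_suffix(".json").exists():
            model = _load_model(rfs_stem)
            risk = predict_risk(model, expr_g)
            lt = out_g.longterm_class
            rel = risk[[i for i, v in enumerate(lt) if v == "relapsed"]]
            ccr = risk[[i for i, v in enumerate(lt) if v == "CCR"]]
            if rel.size and ccr.size:
                entry["rfs_rank_sum_p"] = float(f"{rank_sum_test(rel, ccr):.3g}")
                entry["n_relapsed"], entry["n_ccr"] = int(rel.size), int(ccr.size)

        report[f"subgroup_{g}"] = entry

    Path("results/report.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
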