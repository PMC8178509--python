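#!/usr/bin/env python
"""Generate the paired synthetic training/test study and write it to disk.

The study mirrors the shape of the real cohorts the pipeline targets: 370
genes, 200 training and 100 test samples, 4 latent expression subgroups, a
binary early-response outcome (~35% bad responders) and censored
relapse-free survival (~30% censoring).  Writes expression TSVs, outcome
CSVs and the generator ground truth under results/data/.
"""

import json
from pathlib import Path

import numpy as np

from allsub import SyntheticConfig, generate_cohorts, write_expression, write_outcomes

OUT = Path("results/data")
SEED = 20210513


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)
    study = generate_cohorts(cfg)

    for name, cohort in (("train", study.train), ("test", study.test)):
        write_expression(cohort.expression, OUT / f"{name}_expression.tsv")
        write_outcomes(cohort.outcomes, OUT / f"{name}_outcomes.csv")
        truth = {
            "labels": cohort.truth.labels.tolist(),
            "outcome_gene_idx": [a.tolist() for a in cohort.truth.outcome_gene_idx],
        }
        (OUT / f"{name}_truth.json").write_text(json.dumps(truth))

    ev = study.train.outcomes.rfs_event
    bad = np.mean([v == "bad" for v in study.train.outcomes.early_response])
    print(f"wrote study to {OUT}/ (seed {SEED})")
    print(f"train: {study.train.expression.n_genes} genes x "
          f"{study.train.expression.n_samples} samples, "
          f"{bad:.0%} bad responders, {1 - ev.mean():.0%} censored")
    print(f"test:  {study.test.expression.n_samples} samples")


if __name__ == "__main__":
    main()
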