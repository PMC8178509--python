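# allsub — expression subgrouping and outcome prediction for B-precursor ALL

`allsub` implements a two-step ("subgroup, then predict") modelling strategy
for paediatric B-precursor acute lymphoblastic leukaemia gene-expression
cohorts. High-risk B-ALL is molecularly heterogeneous: a single prognostic
gene signature fitted across all patients underperforms, while models fitted
inside known genetic subtypes starve for samples. The middle road taken here
is to *learn* expression subgroups unsupervisedly and fit small penalized
outcome models within each subgroup.

The pipeline:

1. **Gene filtering** — keep genes expressed above background
   (value > 100 in > 10% of samples) with coefficient of variation > 1;
   analyses use the intersection of the two cohorts' filtered sets.
2. **Subgrouping by NMF** — factorize the training matrix V ≈ W·H
   (Lee–Seung multiplicative updates for the generalized Kullback–Leibler
   divergence D(V‖WH)); sample *j* joins subgroup *i* = argmaxᵢ h*ᵢⱼ*.
   The rank *r* (number of subgroups) is chosen by **minimum description
   length**: total bits to encode W, H and the residual V − W·H under an
   empirical-histogram or fitted-distribution coding. Stability is assessed
   with consensus matrices over stochastic runs, and the final factors
   average the top 20 of 60 runs (scale-normalized, permutation-aligned).
3. **Test-cohort projection** — H′ = W⁺·V′ with the Moore–Penrose
   pseudoinverse W⁺ = T·D⁺·Sᵀ from the SVD W = S·D·Tᵀ; assignment is again
   column-wise argmax (on signed coefficients).
4. **Per-subgroup outcome models** — elastic-net (α = 0.8) logistic
   regression for the binary early-response outcome (MRD status) and
   elastic-net Cox regression for relapse-free survival (RFS), each with a
   10-fold cross-validated deviance curve defining λ_min and λ_1se. MRD
   models are extracted at λ_1se, falling back to λ_min when the λ_1se model
   is degenerate (all coefficients zero); RFS models use the simplest
   non-degenerate point on the path.
5. **Evaluation** — ROC/AUC for binary predictions, Harrell's concordance
   and IPCW cumulative/dynamic time-dependent ROC for risk scores, and a
   one-sided Wilcoxon rank-sum test comparing predicted risk between
   relapsed and long-term-remission (CCR) patients.

A first-class synthetic-data generator (`allsub.synthetic`) emulates the
statistical structure the pipeline assumes — low-rank non-negative expression
with latent subgroups, subgroup-specific sparse outcome signatures, and
censored survival — so every stage is testable without downloads.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort pair (370 genes; 200 training and 100 test samples; 4 planted
subgroups):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_filter_genes.py
python analysis/03_select_rank.py
python analysis/04_subgroup_training.py
python analysis/05_fit_models.py
python analysis/06_project_and_evaluate.py
```

Output from a run (seed 20210513, fixed in the scripts):

```
filter kept 117 (train) and 115 (test) of 370 genes; intersection 114
 rank  bits_histogram  bits_fitted
    2          156965       157259
    3          137101       146072
    4          107271       139144
    5          111373       140020
    6          115386       146436
selected rank: 4 (histogram coding), 4 (fitted coding)
train subgroup sizes: {1: 50, 2: 50, 3: 50, 4: 50}
subgroup 1 mrd: k=10 lambda=0.122 AUC=1.000
subgroup 1 rfs: k=5  lambda=0.611 c=0.888 tdAUC={1: 0.993, 2: 0.984, 5: 0.931}
subgroup 3 mrd: k=3  lambda=0.086 AUC=0.990
...
"subgroup_1": {"n": 25, "mrd_auc": 0.96, "rfs_rank_sum_p": 1.1e-05, ...}
```

Reading this: the gene filter recovers essentially the planted signature
genes (114 of 120); the description length is minimized at the true rank 4
under both codings; each training subgroup's extracted logistic model
separates good from bad early responders (AUC ≈ 0.99–1.0 in training,
0.91–0.97 in the projected test subgroups); and the one- or few-gene Cox
models yield risk scores that clearly separate relapsed from CCR test
patients (rank-sum p < 0.001 in all four subgroups).

For real cohorts, `allsub.read_expression` / `read_outcomes` accept
TSV/CSV matrices (genes × samples, preprocessed to a linear expression
scale) and the same drivers apply with the default background threshold
of 100.

## Layout

```
src/allsub/        data_io, nmf, rank_mdl, projection, enet, evaluation,
                   synthetic, pipeline (run_pipeline orchestrates everything)
analysis/          numbered narrative drivers writing under results/
tests/             pytest suite incl. property-based acceptance checks
docs/methods.md    modelling and design notes
```
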