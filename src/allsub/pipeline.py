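"""End-to-end orchestration: filter -> rank-select -> factorize -> assign ->
per-subgroup outcome models -> project test cohort -> evaluate.

All randomness flows from one master seed through a named-stream scheme
(`numpy.random.SeedSequence` children), so two runs with the same config are
byte-identical.  Subgroups that cannot support a model (a single outcome
class, too few events) skip that model with a logged reason; evaluation
metrics that need both classes report "not evaluable" rather than failing the
run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .data_io import ExpressionMatrix, GeneFilterConfig, OutcomeTable, filter_genes, intersect_gene_sets
from .enet import extract_model, fit_cox_path, fit_logistic_path, predict_logistic, predict_risk
from .evaluation import concordance, ipcw_td_roc, rank_sum_test, roc_auc
from .nmf import assign_subgroups, average_top_runs, nmf_multirun
from .projection import align_genes, assign_projected, project_cohort
from .rank_mdl import select_rank

logger = logging.getLogger(__name__)

_DAYS_PER_YEAR = 365.25


@dataclass
class PipelineConfig:
    """Inputs and tuning parameters of the full analysis."""

    train_expr: ExpressionMatrix
    train_outcomes: OutcomeTable
    test_expr: ExpressionMatrix
    test_outcomes: OutcomeTable
    gene_filter: GeneFilterConfig | None = None
    apply_gene_filter: bool = True
    rank_candidates: Sequence[int] = tuple(range(2, 13))
    runs_per_rank: int = 30
    mdl_method: str = "histogram"
    n_runs: int = 60
    top_k: int = 20
    alpha: float = 0.8
    n_folds: int = 10
    n_lambda: int = 100
    mrd_policy: str = "1se_fallback_min"
    rfs_policy: str = "simplest_nondegenerate"
    horizons_years: Sequence[float] = (1.0, 2.0, 5.0)
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k > self.n_runs:
            raise ValueError("top_k cannot exceed n_runs")
        if not self.rank_candidates:
            raise ValueError("rank_candidates must be non-empty")


@dataclass
class PipelineReport:
    """Aggregated outputs of one pipeline run."""

    selected_rank: int
    rank_table: list[dict]
    genes_used: list[str]
    n_genes_train_filtered: int
    n_genes_test_filtered: int
    train_subgroup_sizes: dict[int, int]
    test_subgroup_sizes: dict[int, int]
    train_labels: dict[str, int]
    test_labels: dict[str, int]
    models: dict[str, dict]
    evaluation: dict[str, dict]
    skipped: list[dict]
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(asdict(self), indent=indent, default=default)


def _stream_seeds(master: int, names: Sequence[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)}


def _binary_early(outcomes: OutcomeTable, idx: np.ndarray):
    """0/1 vector (bad=1) and the subset of idx with a non-missing early response."""
    er = outcomes.early_response
    if er is None:
        return np.array([]), np.array([], dtype=int)
    keep = np.array([er[i] is not None for i in idx])
    sel = idx[keep]
    y = np.array([1.0 if er[i] == "bad" else 0.0 for i in sel])
    return y, sel


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    seeds = _stream_seeds(cfg.seed, ["rank", "nmf", "mrd", "rfs"])

    # ------------------------------------------------------------- gene filter
    gf = cfg.gene_filter or GeneFilterConfig()
    if cfg.apply_gene_filter:
        genes_train = filter_genes(cfg.train_expr, gf)
        genes_test = filter_genes(cfg.test_expr, gf)
    else:
        genes_train = list(cfg.train_expr.gene_ids)
        genes_test = list(cfg.test_expr.gene_ids)
    genes = intersect_gene_sets(genes_train, genes_test)
    logger.info("gene filter: %d train, %d test, %d in intersection",
                len(genes_train), len(genes_test), len(genes))
    if len(genes) < 2:
        raise ValueError("fewer than 2 genes shared by both cohorts after filtering")
    train = cfg.train_expr.subset_genes(genes)
    test = cfg.test_expr.subset_genes(genes)
    V = train.values

    # ---------------------------------------------------------- rank selection
    candidates = list(cfg.rank_candidates)
    rank_table: list[dict] = []
    if len(candidates) == 1:
        rank = candidates[0]
        logger.info("single rank candidate %d: skipping MDL sweep", rank)
    else:
        sel = select_rank(V, candidates, runs_per_rank=cfg.runs_per_rank,
                          method=cfg.mdl_method, seed=seeds["rank"],
                          max_iter=cfg.nmf_max_iter, tol=cfg.nmf_tol)
        rank = sel.selected_rank
        rank_table = [
            {"rank": d.rank, "bits_histogram": d.bits_histogram, "bits_fitted": d.bits_fitted}
            for d in sel.table
        ]
        logger.info("MDL (%s coding) selected rank %d", cfg.mdl_method, rank)

    # -------------------------------------------------- factorize and subgroup
    ensemble = nmf_multirun(V, rank, n_runs=cfg.n_runs, base_seed=seeds["nmf"],
                            max_iter=cfg.nmf_max_iter, tol=cfg.nmf_tol)
    averaged = average_top_runs(ensemble, cfg.top_k)
    W, H = averaged.W, averaged.H
    train_assign = assign_subgroups(H, train.sample_ids)

    H_prime = project_cohort(W, align_genes(genes, test))
    test_assign = assign_projected(H_prime, test.sample_ids)

    train_sizes = {g: int((train_assign.labels == g).sum()) for g in range(1, rank + 1)}
    test_sizes = {g: int((test_assign.labels == g).sum()) for g in range(1, rank + 1)}
    logger.info("subgroup sizes: train %s, test %s", train_sizes, test_sizes)

    # ------------------------------------------------------ per-subgroup models
    models: dict[str, dict] = {}
    evaluation: dict[str, dict] = {}
    skipped: list[dict] = []
    X_train = V.T  # samples x genes
    train_out = cfg.train_outcomes.subset(train.sample_ids)
    test_out = cfg.test_outcomes.subset(test.sample_ids)

    for g in range(1, rank + 1):
        idx = np.where(train_assign.labels == g)[0]
        test_idx = np.where(test_assign.labels == g)[0]
        sub_train_expr = train.subset_samples([train.sample_ids[i] for i in idx])
        sub_test_expr = (test.subset_samples([test.sample_ids[i] for i in test_idx])
                         if test_idx.size else None)

        # ---- MRD (logistic)
        y, sel = _binary_early(train_out, idx)
        key = f"subgroup_{g}_mrd"
        if np.unique(y).size < 2 or np.bincount(y.astype(int)).min() < 2:
            skipped.append({"model": key, "reason":
                            "early response not informative (single class or <2 per class)"})
            logger.info("skipping %s: single outcome class", key)
        else:
            n_folds = max(3, min(cfg.n_folds, int(np.bincount(y.astype(int)).min())))
            if n_folds < cfg.n_folds:
                logger.warning("%s: reducing CV folds to %d for %d samples", key, n_folds, sel.size)
            path = fit_logistic_path(
                X_train[sel], y, gene_ids=genes, alpha=cfg.alpha, n_folds=n_folds,
                seed=seeds["mrd"] + g, n_lambda=cfg.n_lambda)
            model = extract_model(path, cfg.mrd_policy, subgroup=g)
            models[key] = {
                "family": "logistic", "policy": cfg.mrd_policy, "k": model.k,
                "lambda": model.lambda_used, "genes": model.gene_ids,
                "beta": model.beta, "intercept": model.intercept,
                "degenerate": model.degenerate,
            }
            ev = {}
            if not model.degenerate:
                sub_expr_sel = train.subset_samples([train.sample_ids[i] for i in sel])
                prob = predict_logistic(model, sub_expr_sel)
                auc, _, _ = roc_auc(prob, y)
                ev["train_auc"] = auc
                ev["n_train"] = int(sel.size)
                if sub_test_expr is not None:
                    y_te, sel_te = _binary_early(test_out, test_idx)
                    if np.unique(y_te).size == 2:
                        expr_te = test.subset_samples([test.sample_ids[i] for i in sel_te])
                        prob_te = predict_logistic(model, expr_te)
                        auc_te, _, _ = roc_auc(prob_te, y_te)
                        ev["test_auc"] = auc_te
                        ev["n_test"] = int(sel_te.size)
                    else:
                        ev["test_auc"] = "not evaluable"
            evaluation[key] = ev

        # ---- RFS (Cox)
        key = f"subgroup_{g}_rfs"
        if train_out.rfs_time is None:
            skipped.append({"model": key, "reason": "no survival outcome in training cohort"})
        else:
            t_all, e_all = train_out.rfs_time[idx], train_out.rfs_event[idx]
            keep = ~np.isnan(t_all)
            sel = idx[keep]
            t, e = t_all[keep], e_all[keep]
            if e.sum() < 2 or sel.size < 6:
                skipped.append({"model": key, "reason": "fewer than 2 events or too few samples"})
                logger.info("skipping %s: insufficient events", key)
            else:
                n_folds = max(3, min(cfg.n_folds, int(min(e.sum(), (1 - e).sum())) or 3))
                path = fit_cox_path(
                    X_train[sel], t, e, gene_ids=genes, alpha=cfg.alpha,
                    n_folds=n_folds, seed=seeds["rfs"] + g, n_lambda=cfg.n_lambda)
                model = extract_model(path, cfg.rfs_policy, subgroup=g)
                models[key] = {
                    "family": "cox", "policy": cfg.rfs_policy, "k": model.k,
                    "lambda": model.lambda_used, "genes": model.gene_ids,
                    "beta": model.beta, "degenerate": model.degenerate,
                }
                ev = {}
                if not model.degenerate:
                    expr_sel = train.subset_samples([train.sample_ids[i] for i in sel])
                    risk = predict_risk(model, expr_sel)
                    try:
                        ev["train_concordance"] = concordance(risk, t, e)
                    except ValueError as exc:
                        ev["train_concordance"] = f"not evaluable: {exc}"
                    ev["n_train"] = int(sel.size)
                    td = {}
                    for hy in cfg.horizons_years:
                        try:
                            auc_h, _, _ = ipcw_td_roc(risk, t, e, hy * _DAYS_PER_YEAR)
                            td[str(hy)] = auc_h
                        except ValueError as exc:
                            td[str(hy)] = f"not evaluable: {exc}"
                    ev["train_td_auc"] = td
                    # test: one-sided rank-sum of risk, relapsed vs CCR
                    lt = test_out.longterm_class
                    if sub_test_expr is not None and lt is not None:
                        rel = [i for i in test_idx if lt[i] == "relapsed"]
                        ccr = [i for i in test_idx if lt[i] == "CCR"]
                        if rel and ccr:
                            r_rel = predict_risk(model, test.subset_samples(
                                [test.sample_ids[i] for i in rel]))
                            r_ccr = predict_risk(model, test.subset_samples(
                                [test.sample_ids[i] for i in ccr]))
                            ev["test_rank_sum_p"] = rank_sum_test(r_rel, r_ccr)
                            ev["n_test_relapsed"] = len(rel)
                            ev["n_test_ccr"] = len(ccr)
                        else:
                            ev["test_rank_sum_p"] = "not evaluable"
                evaluation[key] = ev

    return PipelineReport(
        selected_rank=rank,
        rank_table=rank_table,
        genes_used=genes,
        n_genes_train_filtered=len(genes_train),
        n_genes_test_filtered=len(genes_test),
        train_subgroup_sizes=train_sizes,
        test_subgroup_sizes=test_sizes,
        train_labels=dict(zip(train.sample_ids, train_assign.labels.tolist())),
        test_labels=dict(zip(test.sample_ids, test_assign.labels.tolist())),
        models=models,
        evaluation=evaluation,
        skipped=skipped,
        provenance={"package": "allsub", "seed": cfg.seed,
                    "stream_seeds": seeds, "alpha": cfg.alpha,
                    "n_runs": cfg.n_runs, "top_k": cfg.top_k},
    )
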