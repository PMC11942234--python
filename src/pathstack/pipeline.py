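"""End-to-end orchestration of feature selection, model selection and stacking.

Stage order: enzyme-universe restriction → differential expression → gene-set
enrichment → PC1-variance pathway gating → parent–child pruning → loading-based
representative genes → adversarial-permutation gene filter with cross-model
majority vote → per-model clean + corrupted evaluation → composite-score
ranking → softmax-weighted stacking → stacking evaluation through the same
harness.

Every random draw is traceable to one master seed: each stage derives a child
seed by hashing the stage name, so toggling one stage never shifts another's
randomness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import diff_expression as de
from . import pathway_analysis as pa
from . import robustness as rb
from . import model_selection as ms
from . import stacking as st
from .core_data import ExpressionDataset, GeneList, GeneSetCollection, restrict_to_gene_list
from .models import MODEL_NAMES

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "child_seed"]


def child_seed(master: int, stage: str) -> int:
    """Stable per-stage child seed below 2^31, derived from the master seed."""
    digest = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    fc_threshold: float = 1.5
    de_alpha: float = 0.05
    enrich_alpha: float = 0.05
    min_pathway_size: int = 5
    v_threshold: float = 0.7
    power_alpha: float = 0.5
    loading_coverage: float = 0.95
    retention_quantile: float = 0.95
    subset_fraction: float = 1.0
    n_permutations: int = 100
    mislabel_fraction: float = 0.2
    n_reps: int = 100
    n_folds: int = 5
    score_alpha: float = 2.0
    score_beta: float = -1.0
    score_gamma: float = 0.1
    seed: int = 42
    models: list[str] = field(default_factory=lambda: list(MODEL_NAMES))
    evaluate_stacking: bool = True

    def validate(self) -> None:
        checks = {
            "fc_threshold": self.fc_threshold >= 1,
            "de_alpha": 0 < self.de_alpha < 1,
            "enrich_alpha": 0 < self.enrich_alpha < 1,
            "min_pathway_size": self.min_pathway_size >= 1,
            "v_threshold": 0 < self.v_threshold < 1,
            "power_alpha": self.power_alpha > 0,
            "loading_coverage": 0 < self.loading_coverage <= 1,
            "retention_quantile": 0 < self.retention_quantile <= 1,
            "subset_fraction": 0 < self.subset_fraction <= 1,
            "mislabel_fraction": 0 <= self.mislabel_fraction < 1,
            "n_permutations": self.n_permutations >= 1,
            "n_reps": self.n_reps >= 1,
            "n_folds": self.n_folds >= 2,
            "models": all(m in MODEL_NAMES for m in self.models),
        }
        bad = [k for k, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid configuration values: {bad}")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, report: dict | None = None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.report = report or {}


def run_pipeline(
    ds: ExpressionDataset,
    gene_sets: GeneSetCollection,
    enzyme_list: GeneList | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    stop_after: str | None = None,
) -> dict:
    """Run the full pipeline and return a machine-readable report.

    Writes per-stage TSVs plus ``report.json`` to ``out_dir`` when given. On a
    stage failure, raises :class:`PipelineError` carrying the partial report.
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(cfg), "stages": []}

    def log(stage: str, **info):
        report["stages"].append({"stage": stage, **info})

    def fail(stage: str, msg: str):
        report["error"] = {"stage": stage, "message": msg}
        _dump(report, out, "report.partial.json")
        raise PipelineError(stage, msg, report)

    # -- restrict ----------------------------------------------------------
    stage = "restrict"
    try:
        ds.validate_for_classification()
        if enzyme_list is not None:
            ds_r = restrict_to_gene_list(ds, enzyme_list)
        else:
            ds_r = ds
    except (ValueError, KeyError) as e:
        fail(stage, str(e))
    log(stage, genes_in=ds.n_genes, genes_out=ds_r.n_genes, samples=ds_r.n_samples)

    # -- differential expression ------------------------------------------
    stage = "diff_expression"
    try:
        per_contrast = de.de_test_all_contrasts(ds_r)
        degs = de.union_deg_list(per_contrast, cfg.fc_threshold, cfg.de_alpha)
    except ValueError as e:
        fail(stage, str(e))
    if out is not None:
        _write_de(per_contrast, out / "de_results.tsv")
    log(stage, genes_in=ds_r.n_genes, genes_out=len(degs), contrasts=len(per_contrast))
    if len(degs) == 0:
        fail(stage, "no differentially expressed genes at the configured thresholds")

    # -- enrichment --------------------------------------------------------
    stage = "enrichment"
    universe = GeneList(ds_r.genes)
    try:
        enriched = pa.enrich(
            degs, universe, gene_sets, cfg.min_pathway_size, cfg.enrich_alpha
        )
    except ValueError as e:
        fail(stage, str(e))
    if out is not None:
        _write_rows(
            out / "enrichment.tsv",
            ["pathway", "overlap", "size_in_universe", "p_value", "adj_p_value"],
            [
                (r.pathway, r.overlap, r.pathway_size_in_universe, r.p_value, r.adj_p_value)
                for r in enriched
            ],
        )
    log(stage, pathways_in=len(gene_sets), pathways_out=len(enriched))
    if not enriched:
        fail(stage, "no pathway is significantly enriched")

    # -- pathway variance gate --------------------------------------------
    stage = "pathway_selection"
    ds_log = ds_r.log2p()
    uni_set = universe.as_set()
    loadings: dict[str, pa.LoadingVector] = {}
    triples: list[tuple[str, int, float]] = []
    for r in enriched:
        members = sorted(gene_sets.sets[r.pathway] & uni_set)
        if len(members) < cfg.min_pathway_size:
            continue
        try:
            v, lv = pa.pc1_variance_fraction(ds_log, members, standardize=True)
        except ValueError:
            continue  # degenerate (all-constant) pathway submatrix
        lv.pathway = r.pathway
        loadings[r.pathway] = lv
        triples.append((r.pathway, len(members), v))
    try:
        scored = pa.select_pathways(triples, cfg.v_threshold, cfg.power_alpha)
    except ValueError as e:
        fail(stage, str(e))
    passing = {s.pathway for s in scored if s.passes}
    if out is not None:
        _write_rows(
            out / "pathway_scores.tsv",
            ["pathway", "k", "V", "V_prime", "passes"],
            [(s.pathway, s.k, s.V, s.V_prime, s.passes) for s in scored],
        )
    log(stage, pathways_in=len(triples), pathways_out=len(passing))
    if not passing:
        fail(stage, "no pathway passes the V/V' gate")

    # -- parent–child pruning ---------------------------------------------
    stage = "pruning"
    try:
        pruned = pa.prune_parent_pathways(passing, gene_sets)
    except ValueError as e:
        fail(stage, str(e))
    log(stage, pathways_in=len(passing), pathways_out=len(pruned))

    # -- representative genes ---------------------------------------------
    stage = "representative_genes"
    candidates: list[str] = []
    for name in sorted(pruned):
        reps = pa.select_representative_genes(loadings[name], cfg.loading_coverage)
        candidates.extend(reps)
    candidate_genes = GeneList(candidates)
    log(stage, pathways_in=len(pruned), genes_out=len(candidate_genes))
    if len(candidate_genes) == 0:
        fail(stage, "no representative genes selected")

    # -- adversarial permutation filter -----------------------------------
    stage = "robustness_filter"
    profiles: dict[str, list[rb.RobustnessProfile]] = {}
    try:
        for m in cfg.models:
            profiles[m] = rb.permutation_profile(
                ds_r,
                candidate_genes,
                m,
                subset_fraction=cfg.subset_fraction,
                n_permutations=cfg.n_permutations,
                seed=child_seed(cfg.seed, f"robustness:{m}"),
                retention_quantile=cfg.retention_quantile,
            )
        selected = rb.majority_vote_retention(profiles, cfg.models)
    except ValueError as e:
        fail(stage, str(e))
    if out is not None:
        _write_rows(
            out / "robustness.tsv",
            ["gene", "model", "true_importance", "n_below", "retained"],
            [
                (p.gene, p.model, p.true_importance, p.n_below, p.retained)
                for m in cfg.models
                for p in profiles[m]
            ],
        )
    log(stage, genes_in=len(candidate_genes), genes_out=len(selected))
    if len(selected) == 0:
        fail(stage, "no gene survives the adversarial-permutation filter")
    report["selected_genes"] = list(selected)
    report["selected_pathways"] = sorted(pruned)
    if stop_after == "features":
        if out is not None:
            with open(out / "selected_genes.txt", "w") as fh:
                fh.write("\n".join(report["selected_genes"]) + "\n")
        _dump(report, out, "report.json")
        return report

    # -- model evaluation --------------------------------------------------
    stage = "model_evaluation"
    metrics: list[ms.ModelMetrics] = []
    oof: dict[str, np.ndarray] = {}
    try:
        for m in cfg.models:
            mm, cv = ms.evaluate_model(
                ds_r,
                selected,
                m,
                label_task="task",
                mislabel_fraction=cfg.mislabel_fraction,
                n_reps=cfg.n_reps,
                seed=cfg.seed,
                n_folds=cfg.n_folds,
                alpha=cfg.score_alpha,
                beta=cfg.score_beta,
                gamma=cfg.score_gamma,
            )
            metrics.append(mm)
            oof[m] = cv.oof_proba
    except ValueError as e:
        fail(stage, str(e))
    ranking = sorted(metrics, key=lambda m: -m.final_score)
    report["model_metrics"] = [_metrics_row(m) for m in ranking]
    log(stage, models=len(metrics), best=ranking[0].model)

    # -- stacking ----------------------------------------------------------
    stage = "stacking"
    try:
        ensemble = st.fit_stacking(
            ds_r, selected, metrics, oof, seed=child_seed(cfg.seed, "stacking")
        )
    except ValueError as e:
        fail(stage, str(e))
    report["stacking"] = {
        "scores": ensemble.scores,
        "weights": ensemble.weights,
        "score_vs_ranking_note": (
            "Score_i sums CS with a plus sign while the ranking composite "
            "weights CS negatively; both printed definitions are applied verbatim."
        ),
    }
    log(stage, base_models=len(ensemble.base_models))

    if cfg.evaluate_stacking:
        stage = "stacking_evaluation"
        try:
            mm_stack, _ = ms.evaluate_model(
                ds_r,
                selected,
                st.stacking_factory(ensemble.weights, cfg.models),
                model_name="Stacking",
                mislabel_fraction=cfg.mislabel_fraction,
                n_reps=cfg.n_reps,
                seed=cfg.seed,
                n_folds=cfg.n_folds,
                alpha=cfg.score_alpha,
                beta=cfg.score_beta,
                gamma=cfg.score_gamma,
            )
        except ValueError as e:
            fail(stage, str(e))
        report["model_metrics"].append(_metrics_row(mm_stack))
        log(stage, final_score=mm_stack.final_score)

    if out is not None:
        _write_rows(
            out / "model_metrics.tsv",
            ["model", "task", "F1", "F1_prime", "CS", "CR", "final_score"],
            [
                (
                    r["model"],
                    r["label_task"],
                    r["F1"],
                    r["F1_prime"],
                    r["CS"],
                    r["CR"],
                    r["final_score"],
                )
                for r in report["model_metrics"]
            ],
        )
        with open(out / "selected_genes.txt", "w") as fh:
            fh.write("\n".join(report["selected_genes"]) + "\n")
    _dump(report, out, "report.json")
    return report


def _metrics_row(m: ms.ModelMetrics) -> dict:
    row = asdict(m)
    row["coefficients"] = list(m.coefficients)
    return row


def _dump(report: dict, out: Path | None, name: str) -> None:
    if out is not None:
        with open(out / name, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)


def _write_rows(path: Path, header: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_de(per_contrast, path: Path) -> None:
    _write_rows(
        path,
        ["gene", "contrast", "log2_fold_change", "p_value", "adj_p_value"],
        [
            (r.gene, label, r.log2_fold_change, r.p_value, r.adj_p_value)
            for label, results in per_contrast.items()
            for r in results
        ],
    )
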