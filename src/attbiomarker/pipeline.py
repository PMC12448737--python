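"""End-to-end orchestration of the biomarker-discovery workflow.

Stages, in order: (1) per-study statistics, the permissive p-value
prefilter, and the cross-study common-gene matrix S; (2) Fisher-score
ranking with a grid of candidate subset sizes, each evaluated by
cross-validated classification — the winner advances; (3) mRMR
refinement of the winner over a second size grid, evaluated the same
way; (4) per-study DEG selection and intersection with the final
subset; (5) optional degree-based hub ranking on a supplied edge list.

The winner of each round is the subset with the highest held-out test
accuracy (ties: higher AUC, then smaller size). One stratified 80/20
split, fixed at pipeline start from the master seed, is reused by every
round so subsets are compared on identical samples. Each stage draws
its randomness from a seed derived from the master seed and the stage
name (CRC-32), so stages can be re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from attbiomarker import attcnn, evaluation, expression_io, fisher_select, mrmr_select
from attbiomarker.expression_io import DatasetBundle, LabeledExpressionMatrix
from attbiomarker.network_hubs import read_edge_list, top_hubs_by_degree
from attbiomarker.synthetic_data import SyntheticSpec, generate_multistudy

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; loadable from YAML or JSON.

    Provide either ``studies`` (list of dicts with keys name/expression/
    labels and optionally stats, pointing at TSV files) or ``synthetic``
    (a :class:`SyntheticSpec` or its field dict).
    """

    studies: list[dict] | None = None
    synthetic: SyntheticSpec | dict | None = None
    prefilter_p: float = 0.25
    fisher_sizes: list[int] | str = "auto"
    mrmr_sizes: list[int] = field(default_factory=lambda: [2500, 2000, 1500, 1000])
    mrmr_bins: int = 5
    deg_p: float = 0.05
    deg_logfc: float = 1.0
    variant: str = "baseline"
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 5
    test_fraction: float = 0.2
    cv_folds: int = 5
    seed: int = 0
    out_dir: str | None = None
    edge_list: str | None = None

    def __post_init__(self) -> None:
        if (self.studies is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of studies / synthetic")
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticSpec(**self.synthetic)
        if not (0 < self.prefilter_p <= 1):
            raise ValueError("prefilter_p must lie in (0, 1]")
        if not (0 < self.deg_p < 1):
            raise ValueError("deg_p must lie in (0, 1)")
        if self.variant not in attcnn.ABLATION_VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")


@dataclass
class PipelineReport:
    """Artifacts of one run; every gene set is reproducible from the
    logged seeds and config hash."""

    config_hash: str
    seed: int
    common_genes: list[str]
    fisher_sizes: list[int]
    fisher_reports: dict[int, evaluation.EvalReport]
    fisher_winner_size: int
    fisher_winner_genes: list[str]
    mrmr_sizes: list[int]
    mrmr_reports: dict[int, evaluation.EvalReport]
    mrmr_winner_size: int
    mrmr_winner_genes: list[str]
    deg_sets: dict[str, set]
    common_with_degs: list[str]
    hubs: list[tuple[str, int]] | None


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master combined with a CRC-32 of the
    stage name, kept below 2**31."""
    return (master_seed + zlib.crc32(stage.encode())) % (2**31)


def _config_hash(cfg: PipelineConfig) -> str:
    d = asdict(cfg)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_bundles(cfg: PipelineConfig) -> list[DatasetBundle]:
    if cfg.synthetic is not None:
        bundles, _ = generate_multistudy(cfg.synthetic)
        return bundles
    bundles = []
    for st in cfg.studies:
        matrix = expression_io.read_expression_matrix(st["expression"], st["labels"])
        if "stats" in st and st["stats"]:
            stats = expression_io.read_gene_stats(st["stats"])
        else:
            stats = expression_io.per_gene_welch_t(matrix)
        bundles.append(DatasetBundle(name=st["name"], matrix=matrix, stats=stats))
    return bundles


def _model_builder(cfg: PipelineConfig, input_length: int):
    base = attcnn.AttCnnSpec(input_length=input_length)
    if cfg.variant in ("WFAL", "WSAL", "RBAL"):
        base = attcnn.make_two_attention_parent(base)
    spec = attcnn.make_ablation(cfg.variant, base)

    def build(seed: int):
        tc = attcnn.TrainConfig(
            learning_rate=cfg.learning_rate,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            patience=cfg.patience,
            seed=seed,
        )
        return evaluation.AttCnnAdapter(spec, tc)

    return build


def _evaluate_sizes(
    cfg: PipelineConfig,
    matrices: dict[int, LabeledExpressionMatrix],
    plan: evaluation.SplitPlan,
) -> tuple[dict[int, evaluation.EvalReport], int]:
    """Evaluate one matrix per candidate size; return reports and winner.

    Winner: highest held-out test accuracy, ties broken by higher AUC,
    then smaller size.
    """
    reports = {}
    for size, mat in matrices.items():
        logger.info("evaluating subset of %d genes", size)
        builder = _model_builder(cfg, mat.n_genes)
        reports[size] = evaluation.crossval_evaluate(builder, mat, plan)
    winner = min(
        reports,
        key=lambda s: (-reports[s].test_set.acc, -reports[s].test_set.auc, s),
    )
    return reports, winner


def run_attbiomarker(cfg: PipelineConfig) -> PipelineReport:
    """Run the full workflow; see the module docstring for the stages."""
    cfg_hash = _config_hash(cfg)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # stage 1: stats, prefilter, common matrix -----------------------------
    logger.info("[stage filter] loading studies and building common matrix")
    bundles = _load_bundles(cfg)
    gene_sets = [
        expression_io.filter_by_pvalue(b.stats, cfg.prefilter_p) for b in bundles
    ]
    S = expression_io.build_common_matrix(bundles, gene_sets)
    logger.info("[stage filter] common matrix: %d samples x %d genes",
                S.n_samples, S.n_genes)

    plan = evaluation.make_split_plan(
        S.labels, cfg.test_fraction, cfg.cv_folds, seed=stage_seed(cfg.seed, "split")
    )

    # stage 2: Fisher round ------------------------------------------------
    logger.info("[stage fisher] ranking %d genes", S.n_genes)
    ranking = fisher_select.fisher_scores(S)
    if cfg.fisher_sizes == "auto":
        sorted_scores = ranking.scores[ranking.order]
        fisher_sizes = [fisher_select.detect_deflection(sorted_scores)]
    else:
        fisher_sizes = [min(s, S.n_genes) for s in cfg.fisher_sizes]
    fisher_mats = {k: fisher_select.take_top(S, ranking, k) for k in fisher_sizes}
    fisher_reports, fisher_winner = _evaluate_sizes(cfg, fisher_mats, plan)
    S1 = fisher_mats[fisher_winner]
    logger.info("[stage fisher] winner: %d genes (test acc %.4f)",
                fisher_winner, fisher_reports[fisher_winner].test_set.acc)

    # stage 3: mRMR round --------------------------------------------------
    mrmr_sizes = sorted({min(s, S1.n_genes) for s in cfg.mrmr_sizes}, reverse=True)
    logger.info("[stage mrmr] ranking %d genes to max size %d",
                S1.n_genes, max(mrmr_sizes))
    disc = mrmr_select.discretize(S1, n_bins=cfg.mrmr_bins)
    mr = mrmr_select.mrmr_rank(disc, S1.labels, n_select=max(mrmr_sizes))
    mrmr_mats = {
        k: S1.subset_genes([S1.gene_ids[i] for i in mr.order[:k]]) for k in mrmr_sizes
    }
    mrmr_reports, mrmr_winner = _evaluate_sizes(cfg, mrmr_mats, plan)
    S2 = mrmr_mats[mrmr_winner]
    logger.info("[stage mrmr] winner: %d genes (test acc %.4f)",
                mrmr_winner, mrmr_reports[mrmr_winner].test_set.acc)

    # nesting invariant: round-2 ⊆ round-1 ⊆ common genes
    assert set(S2.gene_ids) <= set(S1.gene_ids) <= set(S.gene_ids)

    # stage 4: DEGs and intersection --------------------------------------
    deg_sets = {
        b.name: expression_io.select_degs(b.stats, cfg.deg_p, cfg.deg_logfc)
        for b in bundles
    }
    common_with_degs = expression_io.intersect_deg_with_subset(
        list(deg_sets.values()), set(S2.gene_ids)
    )
    logger.info("[stage degs] %d genes common to DEGs and the final subset",
                len(common_with_degs))

    # stage 5: optional hub ranking ----------------------------------------
    hubs = None
    if cfg.edge_list:
        hubs = top_hubs_by_degree(read_edge_list(cfg.edge_list), k=10)
        logger.info("[stage hubs] top hub: %s", hubs[0] if hubs else None)

    report = PipelineReport(
        config_hash=cfg_hash,
        seed=cfg.seed,
        common_genes=list(S.gene_ids),
        fisher_sizes=fisher_sizes,
        fisher_reports=fisher_reports,
        fisher_winner_size=fisher_winner,
        fisher_winner_genes=list(S1.gene_ids),
        mrmr_sizes=mrmr_sizes,
        mrmr_reports=mrmr_reports,
        mrmr_winner_size=mrmr_winner,
        mrmr_winner_genes=list(S2.gene_ids),
        deg_sets=deg_sets,
        common_with_degs=common_with_degs,
        hubs=hubs,
    )
    if out_dir:
        _write_artifacts(report, out_dir)
    return report


def _metrics_json(rep: evaluation.EvalReport) -> dict:
    return {
        "per_fold": [r.as_dict() for r in rep.per_fold],
        "aggregate": rep.aggregate,
        "test": rep.test_set.as_dict() if rep.test_set else None,
    }


def _write_artifacts(report: PipelineReport, out_dir: Path) -> None:
    (out_dir / "common_genes.txt").write_text("\n".join(report.common_genes) + "\n")
    (out_dir / "fisher_winner_genes.txt").write_text(
        "\n".join(report.fisher_winner_genes) + "\n"
    )
    (out_dir / "mrmr_winner_genes.txt").write_text(
        "\n".join(report.mrmr_winner_genes) + "\n"
    )
    (out_dir / "common_with_degs.txt").write_text(
        "\n".join(report.common_with_degs) + "\n"
    )
    manifest = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "fisher_sizes": report.fisher_sizes,
        "fisher_winner_size": report.fisher_winner_size,
        "mrmr_sizes": report.mrmr_sizes,
        "mrmr_winner_size": report.mrmr_winner_size,
        "n_common_genes": len(report.common_genes),
        "n_common_with_degs": len(report.common_with_degs),
        "hubs": report.hubs,
        "metrics": {
            "fisher": {str(k): _metrics_json(v) for k, v in report.fisher_reports.items()},
            "mrmr": {str(k): _metrics_json(v) for k, v in report.mrmr_reports.items()},
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
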