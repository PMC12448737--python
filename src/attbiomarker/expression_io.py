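"""Expression-matrix I/O, differential-expression filters, and the
cross-study common-gene matrix.

Expression files are tab-separated genes x samples tables (first column
gene id, one column per sample, log2-scale intensities); labels map
sample id to a binary class (1 = case, 0 = control). Per-gene statistics
(p-value, log2 fold-change) can be ingested from external
differential-expression tools or computed in-package with a Welch t
test, which stands in for moderated-t pipelines such as limma when only
the expression matrix is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STATS_COLUMNS = ["gene_id", "p_value", "log_fc", "t_stat", "degenerate"]


@dataclass
class LabeledExpressionMatrix:
    """Samples x genes expression matrix with binary sample labels.

    Attributes
    ----------
    values : ndarray of shape (q, p)
        Continuous expression, rows are samples, columns are genes.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    gene_ids : list of str
        Unique gene identifiers, one per column.
    labels : ndarray of shape (q,)
        Binary class per sample; 1 = case, 0 = control.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.sample_ids = list(self.sample_ids)
        self.gene_ids = list(self.gene_ids)
        q, p = self.values.shape
        if len(self.sample_ids) != q or len(self.labels) != q:
            raise ValueError(
                f"row count {q} != sample_ids {len(self.sample_ids)} "
                f"or labels {len(self.labels)}"
            )
        if len(self.gene_ids) != p:
            raise ValueError(f"column count {p} != gene_ids {len(self.gene_ids)}")
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ValueError(f"duplicated gene id: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicated sample id: {dup!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite expression values after ingestion")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "LabeledExpressionMatrix":
        """Restrict to the given genes, in the given order."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return LabeledExpressionMatrix(
            self.values[:, idx], self.sample_ids, list(gene_ids), self.labels
        )


@dataclass
class DatasetBundle:
    """One study: its expression matrix plus a per-gene statistics table."""

    name: str
    matrix: LabeledExpressionMatrix
    stats: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.stats["gene_id"]) - set(self.matrix.gene_ids)
        if missing:
            raise ValueError(
                f"stats genes absent from matrix: {sorted(missing)[:5]}..."
                if len(missing) > 5
                else f"stats genes absent from matrix: {sorted(missing)}"
            )


def _first_duplicate(items) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression_matrix(expr_path, labels_path) -> LabeledExpressionMatrix:
    """Read a genes x samples TSV plus a sample->label TSV.

    The matrix is transposed to samples x genes; sample order follows the
    label file. Genes containing any missing value are dropped (count
    logged).
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    dup = _first_duplicate(expr.index.tolist())
    if dup is not None:
        raise ValueError(f"duplicated gene id: {dup!r}")

    lab = pd.read_csv(labels_path, sep="\t", header=0)
    lab.columns = ["sample_id", "label"]
    lab["sample_id"] = lab["sample_id"].astype(str)

    expr_samples = set(map(str, expr.columns))
    lab_samples = set(lab["sample_id"])
    if expr_samples != lab_samples:
        missing_labels = sorted(expr_samples - lab_samples)
        missing_expr = sorted(lab_samples - expr_samples)
        parts = []
        if missing_labels:
            parts.append("samples missing labels: " + ", ".join(missing_labels))
        if missing_expr:
            parts.append("labeled samples missing expression: " + ", ".join(missing_expr))
        raise ValueError("; ".join(parts))

    n_before = expr.shape[0]
    expr = expr.dropna(axis=0, how="any")
    n_dropped = n_before - expr.shape[0]
    if n_dropped:
        logger.info("dropped %d gene%s with missing values", n_dropped,
                    "" if n_dropped == 1 else "s")

    order = lab["sample_id"].tolist()
    values = expr[order].to_numpy(dtype=float).T
    return LabeledExpressionMatrix(
        values=values,
        sample_ids=order,
        gene_ids=expr.index.astype(str).tolist(),
        labels=lab["label"].to_numpy(dtype=int),
    )


def read_gene_stats(path) -> pd.DataFrame:
    """Read an externally computed per-gene statistics TSV.

    Expected columns: ``gene_id``, ``p_value``, ``log_fc`` and optionally
    ``t_stat``. Use this to ingest moderated-t outputs (e.g. limma/GEO2R)
    verbatim instead of the in-package Welch stand-in.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "p_value", "log_fc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicated gene id in stats table: {dup!r}")
    pv = df["p_value"].to_numpy(float)
    if ((pv < 0) | (pv > 1)).any() or not np.isfinite(pv).all():
        raise ValueError("p_value must lie in [0, 1]")
    if not np.isfinite(df["log_fc"].to_numpy(float)).all():
        raise ValueError("log_fc must be finite")
    if "t_stat" not in df.columns:
        df["t_stat"] = np.nan
    if "degenerate" not in df.columns:
        df["degenerate"] = False
    return df[STATS_COLUMNS].copy()


def per_gene_welch_t(m: LabeledExpressionMatrix) -> pd.DataFrame:
    """Per-gene Welch two-sample t test, case (label 1) vs control (label 0).

    Returns a table with columns gene_id, p_value, log_fc, t_stat,
    degenerate. ``log_fc`` is mean(case) - mean(control), i.e. a log2
    fold-change when the input matrix is log2-scale. Degrees of freedom
    follow Welch-Satterthwaite. Genes with zero variance in both classes
    get t=0, p=1 when the means agree, and p=0 with a degenerate flag
    when they differ.
    """
    y = m.labels
    x1 = m.values[y == 1]
    x0 = m.values[y == 0]
    n1, n0 = x1.shape[0], x0.shape[0]
    if n1 < 2 or n0 < 2:
        raise ValueError(f"each class needs >=2 samples (case={n1}, control={n0})")

    m1, m0 = x1.mean(axis=0), x0.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v0 = x0.var(axis=0, ddof=1)
    log_fc = m1 - m0

    se2 = v1 / n1 + v0 / n0
    both_zero = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    equal_means = both_zero & (log_fc == 0)
    diff_means = both_zero & (log_fc != 0)
    t = np.where(equal_means, 0.0, t)
    p = np.where(equal_means, 1.0, p)
    t = np.where(diff_means, np.where(log_fc > 0, np.inf, -np.inf), t)
    p = np.where(diff_means, 0.0, p)
    if diff_means.any():
        logger.warning(
            "%d gene(s) have zero variance in both classes but unequal means; "
            "flagged degenerate with p=0", int(diff_means.sum())
        )

    return pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "p_value": p,
            "log_fc": log_fc,
            "t_stat": t,
            "degenerate": diff_means,
        }
    )


def filter_by_pvalue(stats_table: pd.DataFrame, threshold: float = 0.25) -> set[str]:
    """Genes with p_value strictly below ``threshold``.

    The permissive default of 0.25 is a prefilter meant to keep weakly
    associated genes available to the downstream multivariate selection
    rounds, not a significance claim.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    keep = set(stats_table.loc[stats_table["p_value"] < threshold, "gene_id"])
    if not keep:
        warnings.warn("p-value filter retained no genes", stacklevel=2)
    return keep


def select_degs(
    stats_table: pd.DataFrame,
    p_max: float = 0.05,
    min_abs_logfc: float = 1.0,
) -> set[str]:
    """Differentially expressed genes: p < p_max and |logFC| > min_abs_logfc.

    Both inequalities are strict. Whether ``p_value`` is raw or adjusted
    is the caller's choice; the column is used as provided.
    """
    if not (0 < p_max < 1):
        raise ValueError(f"p_max must lie in (0, 1), got {p_max}")
    if min_abs_logfc < 0:
        raise ValueError(f"min_abs_logfc must be >= 0, got {min_abs_logfc}")
    mask = (stats_table["p_value"] < p_max) & (
        stats_table["log_fc"].abs() > min_abs_logfc
    )
    return set(stats_table.loc[mask, "gene_id"])


def build_common_matrix(
    bundles: list[DatasetBundle], gene_sets: list[set[str]]
) -> LabeledExpressionMatrix:
    """Concatenate studies over the intersection of their filtered gene sets.

    The gene universe is the intersection of ``gene_sets`` (one set per
    bundle, typically each study's p-value-filtered genes); samples are
    the concatenation of all bundles' samples in input order; columns are
    sorted lexicographically by gene id. No batch correction is applied.
    """
    if not bundles:
        raise ValueError("need at least one bundle")
    if len(gene_sets) != len(bundles):
        raise ValueError("gene_sets must align 1:1 with bundles")
    common: set[str] = set(gene_sets[0])
    for s in gene_sets[1:]:
        common &= set(s)
    if not common:
        raise ValueError("empty gene intersection across studies")
    genes = sorted(common)

    if len(bundles) > 1:
        logger.warning(
            "concatenating %d studies without batch correction", len(bundles)
        )

    blocks, sample_ids, labels = [], [], []
    all_ids = [sid for b in bundles for sid in b.matrix.sample_ids]
    need_prefix = len(set(all_ids)) != len(all_ids)
    for b in bundles:
        pos = {g: i for i, g in enumerate(b.matrix.gene_ids)}
        idx = [pos[g] for g in genes]
        blocks.append(b.matrix.values[:, idx])
        if need_prefix:
            sample_ids.extend(f"{b.name}:{sid}" for sid in b.matrix.sample_ids)
        else:
            sample_ids.extend(b.matrix.sample_ids)
        labels.append(b.matrix.labels)
    return LabeledExpressionMatrix(
        values=np.vstack(blocks),
        sample_ids=sample_ids,
        gene_ids=genes,
        labels=np.concatenate(labels),
    )


def intersect_deg_with_subset(
    deg_sets: list[set[str]], subset: set[str]
) -> list[str]:
    """Genes common to every DEG set and the selected subset, sorted."""
    common = set(subset)
    for s in deg_sets:
        common &= set(s)
    if not common:
        warnings.warn("no genes common to the DEG sets and the subset", stacklevel=2)
    return sorted(common)
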