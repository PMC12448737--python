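"""Round-1 feature selection with the Fisher criterion.

Each gene i is scored by

    f(i) = sum_x q_x (mu_i^x - mu_i)^2  /  sum_x q_x (sigma_i^x)^2

where x runs over classes, q_x is the class size, mu_i^x / sigma_i^x are
the class mean and *population* (divide-by-n) standard deviation of gene
i, and mu_i is the grand mean. Population standard deviations keep the
per-gene score consistent with the unnormalized scatter sums of the
matrix (trace) form f(S') = tr(M_b) / tr(M_w).

The sorted score curve typically decays steeply then flattens; the
recommended subset size is where the curve bends (the "deflection
point"), automated here by the maximum perpendicular distance to the
chord between the curve's endpoints after min-max normalization of both
axes. Subset sizes remain user-overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from attbiomarker.expression_io import LabeledExpressionMatrix


@dataclass
class FisherRanking:
    """Per-gene Fisher scores with a descending-score ordering.

    ``order`` is a permutation of gene indices sorting scores
    non-increasingly; ties break by ascending original index.
    ``infinite`` flags genes whose within-class variance is exactly zero
    while the classes separate (score sentinel +inf).
    """

    scores: np.ndarray
    order: np.ndarray
    class_stats: dict
    n_classes: int
    infinite: np.ndarray = field(default=None)

    def top_gene_indices(self, k: int) -> np.ndarray:
        return self.order[:k]


@dataclass
class FisherScatter:
    """Between- and within-class scatter matrices on a gene subset."""

    between: np.ndarray
    within: np.ndarray
    grand_mean: np.ndarray
    class_means: dict


def _class_partition(labels: np.ndarray) -> list[tuple[int, np.ndarray]]:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    parts = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
        parts.append((int(c), idx))
    return parts


def fisher_scores(m: LabeledExpressionMatrix) -> FisherRanking:
    """Score every gene by the per-feature Fisher criterion."""
    parts = _class_partition(m.labels)
    X = m.values
    mu = X.mean(axis=0)

    num = np.zeros(m.n_genes)
    den = np.zeros(m.n_genes)
    class_stats = {}
    for c, idx in parts:
        q_x = len(idx)
        mu_x = X[idx].mean(axis=0)
        var_x = X[idx].var(axis=0, ddof=0)  # population variance
        num += q_x * (mu_x - mu) ** 2
        den += q_x * var_x
        class_stats[c] = {"mean": mu_x, "sd": np.sqrt(var_x), "size": q_x}

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / den
    infinite = (den == 0) & (num > 0)
    scores = np.where(infinite, np.inf, scores)
    scores = np.where((den == 0) & (num == 0), 0.0, scores)

    # stable sort on the negated scores: ties keep ascending gene index,
    # +inf sentinels sort first
    order = np.argsort(-scores, kind="stable")
    return FisherRanking(
        scores=scores,
        order=order,
        class_stats=class_stats,
        n_classes=len(parts),
        infinite=infinite,
    )


def fisher_scatter(
    m: LabeledExpressionMatrix, gene_subset: list[int] | np.ndarray
) -> FisherScatter:
    """Explicit between/within scatter matrices on a gene subset (O(r^2))."""
    gene_subset = np.asarray(gene_subset, dtype=int)
    if gene_subset.size == 0:
        raise ValueError("gene subset must be non-empty")
    Z = m.values[:, gene_subset]
    parts = _class_partition(m.labels)

    grand = Z.mean(axis=0)
    r = Z.shape[1]
    Mb = np.zeros((r, r))
    Mw = np.zeros((r, r))
    class_means = {}
    for c, idx in parts:
        mu_x = Z[idx].mean(axis=0)
        d = (mu_x - grand)[:, None]
        Mb += len(idx) * (d @ d.T)
        R = Z[idx] - mu_x
        Mw += R.T @ R
        class_means[c] = mu_x
    return FisherScatter(between=Mb, within=Mw, grand_mean=grand, class_means=class_means)


def fisher_trace_criterion(
    m: LabeledExpressionMatrix, gene_subset: list[int] | np.ndarray
) -> float:
    """Trace-form Fisher criterion tr(M_b)/tr(M_w) on a gene subset.

    Traces are computed directly from sums of squared deviations, so the
    scatter matrices are never materialized; ``fisher_scatter`` provides
    them explicitly when needed.
    """
    gene_subset = np.asarray(gene_subset, dtype=int)
    if gene_subset.size == 0:
        raise ValueError("gene subset must be non-empty")
    Z = m.values[:, gene_subset]
    parts = _class_partition(m.labels)
    grand = Z.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for _, idx in parts:
        mu_x = Z[idx].mean(axis=0)
        tr_b += len(idx) * float(np.sum((mu_x - grand) ** 2))
        tr_w += float(np.sum((Z[idx] - mu_x) ** 2))
    if tr_w == 0:
        raise ValueError("degenerate within-class scatter (tr(M_w) = 0)")
    return tr_b / tr_w


def detect_deflection(sorted_scores: np.ndarray) -> int:
    """Knee of a non-increasing score curve by max chord distance.

    Both axes are min-max normalized, the chord runs from the first to
    the last point, and the returned k (1-based) is the interior index
    with the greatest perpendicular distance to the chord; the
    recommended subset keeps ranks 1..k. Ties break toward the smallest
    index. A flat or perfectly linear curve has no knee: a warning is
    emitted and k = n (keep everything).
    """
    s = np.asarray(sorted_scores, dtype=float)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 scores")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("scores must be non-increasing")

    y_range = s[0] - s[-1]
    if y_range == 0:
        warnings.warn("all scores equal; no deflection point", stacklevel=2)
        return n
    x = np.linspace(0.0, 1.0, n)
    y = (s - s[-1]) / y_range
    # chord from (0, 1) to (1, 0): distance ∝ |x + y - 1|
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    dist[0] = dist[-1] = -np.inf  # interior points only
    if np.max(dist) < 1e-9:
        warnings.warn("score curve is linear; no deflection point", stacklevel=2)
        return n
    return int(np.argmax(dist)) + 1  # 1-based rank


def take_top(
    m: LabeledExpressionMatrix, ranking: FisherRanking, k: int
) -> LabeledExpressionMatrix:
    """Keep the k best-ranked genes, columns in ranked order."""
    if not (1 <= k <= m.n_genes):
        raise ValueError(f"k must lie in [1, {m.n_genes}], got {k}")
    idx = ranking.order[:k]
    return LabeledExpressionMatrix(
        values=m.values[:, idx],
        sample_ids=m.sample_ids,
        gene_ids=[m.gene_ids[i] for i in idx],
        labels=m.labels,
    )
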