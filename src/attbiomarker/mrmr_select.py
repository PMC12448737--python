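"""Round-2 feature selection: greedy minimum-redundancy maximum-relevance.

Relevance of a gene f for the label t is the mutual information D =
I(f, t); redundancy against the already-selected set Phi_s is the mean
pairwise mutual information R = (1/m) sum_{f_i in Phi_s} I(f, f_i). At
each step the gene maximizing D - R (the difference form, "MID") is
appended, step 1 being pure relevance. Mutual information is a plug-in
estimate in nats on equal-frequency discretized expression (B = 5 bins
by default); the label is used as an already-discrete 2-state variable.
All tie-breaks are by ascending original gene index so runs are
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from attbiomarker.expression_io import LabeledExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiscretizedMatrix:
    """Integer-coded expression (samples x genes) plus its bin edges.

    ``realized_bins`` can fall below ``n_bins`` for heavily tied genes
    (duplicated quantile edges are collapsed); constant genes collapse
    to a single bin and are flagged.
    """

    codes: np.ndarray
    bin_edges: list[np.ndarray]
    n_bins: int
    realized_bins: np.ndarray
    constant: np.ndarray


@dataclass
class MrmrRanking:
    """Greedy mRMR selection order with its per-step accounting.

    ``order`` holds selected gene indices in selection order;
    ``relevance``, ``redundancy`` and ``objective`` record, at each
    step's selection time, D, R and D - R for the chosen gene (nats).
    """

    order: np.ndarray
    relevance: np.ndarray
    redundancy: np.ndarray
    objective: np.ndarray


def discretize(m: LabeledExpressionMatrix, n_bins: int = 5) -> DiscretizedMatrix:
    """Per-gene equal-frequency (quantile) binning into integer codes."""
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    X = m.values
    q, p = X.shape
    codes = np.zeros((q, p), dtype=np.int64)
    edges_out: list[np.ndarray] = []
    realized = np.zeros(p, dtype=int)
    constant = np.zeros(p, dtype=bool)

    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    for j in range(p):
        v = X[:, j]
        if v.max() == v.min():
            constant[j] = True
            realized[j] = 1
            edges_out.append(np.empty(0))
            continue
        edges = np.unique(np.quantile(v, qs))
        # drop edges outside the open range so every bin is non-empty
        edges = edges[(edges > v.min()) & (edges < v.max())]
        codes[:, j] = np.searchsorted(edges, v, side="left")
        realized[j] = len(edges) + 1
        edges_out.append(edges)

    n_const = int(constant.sum())
    if n_const:
        logger.info("%d constant gene(s) collapsed to a single bin", n_const)
    return DiscretizedMatrix(
        codes=codes,
        bin_edges=edges_out,
        n_bins=n_bins,
        realized_bins=realized,
        constant=constant,
    )


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two integer code vectors.

    I = sum_{ij} p_ij ln[p_ij / (p_i p_j)] over the empirical joint,
    with 0 ln 0 = 0; the result is clamped to be non-negative against
    floating-point round-off.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"code vectors must be equal-length 1-D, got {a.shape} and {b.shape}")
    n = len(a)
    if n == 0:
        raise ValueError("empty code vectors")
    na = int(a.max()) + 1
    nb = int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    terms = joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])
    # sorted summation: the term multiset is orientation-invariant, so
    # I(a,b) == I(b,a) holds bitwise
    mi = float(np.sum(np.sort(terms)))
    return max(mi, 0.0)


def _mi_columns(codes: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """I(column, ref) for every column of an integer code matrix."""
    return np.array([mutual_information(codes[:, j], ref) for j in range(codes.shape[1])])


def mrmr_rank(
    d: DiscretizedMatrix, labels: np.ndarray, n_select: int
) -> MrmrRanking:
    """Greedy mRMR ranking of ``n_select`` genes against a binary label."""
    labels = np.asarray(labels, dtype=np.int64)
    codes = d.codes
    p = codes.shape[1]
    if not (1 <= n_select <= p):
        raise ValueError(f"n_select must lie in [1, {p}], got {n_select}")
    if codes.shape[0] != len(labels):
        raise ValueError("labels length must match sample count")

    relevance_all = _mi_columns(codes, labels)

    order = np.empty(n_select, dtype=int)
    rel = np.empty(n_select)
    red = np.empty(n_select)
    obj = np.empty(n_select)

    remaining = np.ones(p, dtype=bool)
    red_sum = np.zeros(p)  # sum of I(f, f_i) over selected f_i

    for step in range(n_select):
        m_sel = step  # |Phi_s|
        if m_sel == 0:
            objective = relevance_all.copy()
            redundancy = np.zeros(p)
        else:
            redundancy = red_sum / m_sel
            objective = relevance_all - redundancy
        objective[~remaining] = -np.inf
        j = int(np.argmax(objective))  # first max -> ascending-index ties
        order[step] = j
        rel[step] = relevance_all[j]
        red[step] = redundancy[j] if m_sel else 0.0
        obj[step] = rel[step] - red[step]
        remaining[j] = False
        if step < n_select - 1:
            red_sum[remaining] += _mi_columns(codes[:, remaining], codes[:, j])

    return MrmrRanking(order=order, relevance=rel, redundancy=red, objective=obj)
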