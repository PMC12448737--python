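"""Synthetic multi-study expression data with known ground truth.

The generator emulates the data regime of a small multi-study microarray
compendium: a handful of studies (default 3) with tens of samples each,
thousands of log-scale expression values per sample, a minority of
class-informative genes, and groups of highly correlated near-duplicate
genes that create exactly the redundancy minimum-redundancy selection is
meant to remove.

Model: gene values are Gaussian with per-study per-gene baseline offsets
(uncorrected batch structure); informative genes add a mean shift of
``effect_size`` (in units of the within-class sd) to case samples; each
redundant block shares one latent informative signal re-emitted
``block_size`` times with pairwise correlation ``rho``. Counts, dropout,
probe effects and missingness of real arrays are deliberately absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from attbiomarker.expression_io import (
    DatasetBundle,
    LabeledExpressionMatrix,
    per_gene_welch_t,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_study",
    "generate_multistudy",
    "write_bundle_tsv",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Stated world of the generator.

    Defaults emulate the three-study compendium the workflow targets:
    ~50 samples per study (25 per class), 2000 genes, 50 informative
    genes at effect size 1.5 within-class sd, ten blocks of five
    near-duplicate genes (pairwise correlation 0.95), and a modest
    per-study per-gene baseline offset (sd 0.3) standing in for
    uncorrected batch effects.
    """

    n_per_class: int = 25
    n_genes: int = 2000
    n_informative: int = 50
    effect_size: float = 1.5
    n_redundant_blocks: int = 10
    block_size: int = 5
    rho: float = 0.95
    noise_sd: float = 1.0
    n_studies: int = 3
    study_shift_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant_blocks * self.block_size > self.n_genes:
            raise ValueError("informative + redundant genes exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: informative genes, block structure, mean shifts."""

    informative_ids: list[str]
    redundant_block_map: dict[int, list[str]]
    mean_shift: dict[str, float]


def _gene_universe(spec: SyntheticSpec) -> tuple[list[str], np.ndarray, dict[int, np.ndarray]]:
    """Deterministic gene ids, informative indices and block member indices.

    Planted gene positions are drawn once from the master seed so every
    study shares identities.
    """
    width = len(str(spec.n_genes - 1))
    gene_ids = [f"g{i:0{width}d}" for i in range(spec.n_genes)]
    master = np.random.default_rng(spec.seed)
    n_special = spec.n_informative + spec.n_redundant_blocks * spec.block_size
    special = master.choice(spec.n_genes, size=n_special, replace=False)
    informative = np.sort(special[: spec.n_informative])
    blocks = {}
    off = spec.n_informative
    for b in range(spec.n_redundant_blocks):
        blocks[b] = np.sort(special[off : off + spec.block_size])
        off += spec.block_size
    return gene_ids, informative, blocks


def generate_study(
    spec: SyntheticSpec, study_index: int
) -> tuple[DatasetBundle, GroundTruth]:
    """One study's bundle (matrix + Welch stats) with its ground truth.

    All draws come from ``seed XOR study_index`` (gene identities come
    from the master seed so they are shared across studies).
    """
    gene_ids, informative, blocks = _gene_universe(spec)
    rng = np.random.default_rng(spec.seed ^ (study_index + 1))

    n = 2 * spec.n_per_class
    labels = np.repeat([0, 1], spec.n_per_class)
    delta = spec.effect_size * spec.noise_sd

    baseline = rng.normal(0.0, spec.study_shift_sd, size=spec.n_genes)
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_genes)) + baseline

    shift = np.zeros(spec.n_genes)
    shift[informative] = delta

    # redundant blocks: one latent informative signal per block,
    # re-emitted with pairwise correlation rho between members
    sr, cr = np.sqrt(spec.rho), np.sqrt(1.0 - spec.rho)
    for b, members in blocks.items():
        latent = rng.normal(0.0, spec.noise_sd, size=n)
        for g in members:
            eps = rng.normal(0.0, spec.noise_sd, size=n)
            X[:, g] = baseline[g] + sr * latent + cr * eps
        shift[members] = delta

    X += np.outer(labels, shift)

    matrix = LabeledExpressionMatrix(
        values=X,
        sample_ids=[f"s{study_index}_{i:03d}" for i in range(n)],
        gene_ids=gene_ids,
        labels=labels,
    )
    stats = per_gene_welch_t(matrix)
    truth = GroundTruth(
        informative_ids=[gene_ids[i] for i in informative],
        redundant_block_map={b: [gene_ids[i] for i in mem] for b, mem in blocks.items()},
        mean_shift={gene_ids[i]: float(shift[i]) for i in np.flatnonzero(shift)},
    )
    return DatasetBundle(name=f"study{study_index}", matrix=matrix, stats=stats), truth


def generate_multistudy(
    spec: SyntheticSpec,
) -> tuple[list[DatasetBundle], GroundTruth]:
    """All studies of the spec; shared gene universe and truth."""
    bundles = []
    truth: GroundTruth | None = None
    for s in range(spec.n_studies):
        bundle, truth = generate_study(spec, s)
        bundles.append(bundle)
    assert truth is not None
    return bundles, truth


def write_bundle_tsv(bundle: DatasetBundle, out_dir) -> dict[str, Path]:
    """Emit the TSV formats expression_io reads (byte-deterministic)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = bundle.matrix
    paths = {
        "expression": out_dir / f"{bundle.name}_expression.tsv",
        "labels": out_dir / f"{bundle.name}_labels.tsv",
        "stats": out_dir / f"{bundle.name}_stats.tsv",
    }
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        for j, g in enumerate(m.gene_ids):
            row = "\t".join(f"{v:.6f}" for v in m.values[:, j])
            fh.write(f"{g}\t{row}\n")
    with open(paths["labels"], "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(m.sample_ids, m.labels):
            fh.write(f"{sid}\t{lab}\n")
    bundle.stats.to_csv(paths["stats"], sep="\t", index=False, float_format="%.10g")
    return paths


def write_truth_json(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "informative_ids": truth.informative_ids,
                "redundant_block_map": truth.redundant_block_map,
                "mean_shift": truth.mean_shift,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
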