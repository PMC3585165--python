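"""Two-group synthetic expression datasets with known planted structure.

The generator emulates the data regime of a small case–control muscle
microarray study: ~8800 genes measured on two groups of 7 samples, log2
RMA-style values.  Three structural ingredients are planted:

* a *tissue axis* — each gene draws one baseline level shared by every
  sample, so the gene-abundance profile dominates total variance (the
  first component of a transposed PCA then carries >97% of variance);
* *differential expression* — a minority of genes receive a ±``log2_shift``
  mean offset in the case group;
* *correlation blocks* — groups of genes that co-vary only within one
  group, induced by one latent factor per block
  (``value = sqrt(rho)·factor + sqrt(1−rho)·noise``), which yields the
  target pairwise Pearson correlation in expectation.

When the planted DE set is at least as large as the blocks, block members
are drawn from the DE genes, so the co-expressed disease module is also
differentially expressed — mirroring the structure the pipeline is meant
to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import ExpressionMatrix, SampleAnnotation

__all__ = [
    "Block",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_two_group_dataset",
    "generate_null_dataset",
    "write_truth",
    "read_truth",
]

CONTROL = "control"
CASE = "case"

#: typical RMA log2 grand-mean intensity; shifts nothing downstream.
BASELINE_LEVEL = 7.0


@dataclass(frozen=True)
class Block:
    """A planted correlation block: ``size`` genes at pairwise Pearson
    ``rho``, present only in ``group`` (``"case"`` or ``"control"``)."""

    size: int
    rho: float
    group: str = CASE


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study regime
    (8793 genes, 7 vs 7 samples, 96 shifted genes, one 22-gene case-only
    block near r = 0.97)."""

    n_genes: int = 8793
    n_per_group: int = 7
    n_de: int = 96
    log2_shift: float = 1.5
    tissue_axis_sd: float = 2.5
    noise_sd: float = 0.3
    blocks: tuple[Block, ...] = (Block(size=22, rho=0.97, group=CASE),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be ≥ 1")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be ≥ 1")
        if not 0 <= self.n_de <= self.n_genes:
            raise ConfigurationError("n_de must satisfy 0 ≤ n_de ≤ n_genes")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.tissue_axis_sd < 0:
            raise ConfigurationError("tissue_axis_sd must be ≥ 0")
        total = sum(b.size for b in self.blocks)
        if total > self.n_genes:
            raise ConfigurationError("blocks: total block size exceeds n_genes")
        for b in self.blocks:
            if b.size < 2:
                raise ConfigurationError("blocks: block size must be ≥ 2")
            if not 0 <= b.rho < 1:
                raise ConfigurationError("blocks: rho must satisfy 0 ≤ rho < 1")
            if b.group not in (CONTROL, CASE):
                raise ConfigurationError(
                    f"blocks: group must be {CONTROL!r} or {CASE!r}, got {b.group!r}"
                )


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset.

    ``de_genes`` maps planted DE gene IDs to the sign (+1/−1) of their
    case-group shift; ``block_membership`` maps gene IDs to a block label
    (genes outside every block are absent); ``group_of_block`` maps block
    labels to the group carrying the correlation.
    """

    de_genes: dict[str, int] = field(default_factory=dict)
    block_membership: dict[str, str] = field(default_factory=dict)
    group_of_block: dict[str, str] = field(default_factory=dict)

    def block_genes(self, label: str) -> set[str]:
        return {g for g, b in self.block_membership.items() if b == label}


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_two_group_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Generate one dataset under ``config``; bit-reproducible per seed.

    Controls occupy the first ``n_per_group`` columns, cases the rest.
    """
    rng = np.random.default_rng(config.seed)
    g, m = config.n_genes, 2 * config.n_per_group
    genes = _gene_ids(g)
    samples = [f"{CONTROL}_{i+1}" for i in range(config.n_per_group)] + [
        f"{CASE}_{i+1}" for i in range(config.n_per_group)
    ]
    control_cols = np.arange(config.n_per_group)
    case_cols = np.arange(config.n_per_group, m)

    baseline = BASELINE_LEVEL + config.tissue_axis_sd * rng.standard_normal(g)
    signs = rng.choice([-1, 1], size=config.n_de)
    noise = rng.standard_normal((g, m))

    values = baseline[:, None] + config.noise_sd * noise
    if config.n_de:
        values[np.arange(config.n_de)[:, None], case_cols] += (
            signs[:, None] * config.log2_shift
        )

    # block membership: inside the DE set when it is big enough, after it
    # otherwise (never wrapping past n_genes; config validation guarantees fit)
    total_block = sum(b.size for b in config.blocks)
    start = 0 if config.n_de >= total_block else config.n_de
    if start + total_block > g:
        start = g - total_block
    truth_blocks: dict[str, str] = {}
    group_of_block: dict[str, str] = {}
    offset = start
    for bi, block in enumerate(config.blocks):
        label = f"block{bi + 1}"
        rows = np.arange(offset, offset + block.size)
        offset += block.size
        group_cols = control_cols if block.group == CONTROL else case_cols
        factor = rng.standard_normal(len(group_cols))
        # replace the independent noise with correlated noise in that group
        eps = noise[np.ix_(rows, group_cols)]
        correlated = np.sqrt(block.rho) * factor[None, :] + np.sqrt(1 - block.rho) * eps
        values[np.ix_(rows, group_cols)] = (
            baseline[rows, None] + config.noise_sd * correlated
        )
        # rewriting case-group cells above dropped any DE shift; re-apply it
        if config.n_de and block.group == CASE:
            de_rows = rows[rows < config.n_de]
            if de_rows.size:
                values[np.ix_(de_rows, case_cols)] += (
                    signs[de_rows][:, None] * config.log2_shift
                )
        for r in rows:
            truth_blocks[genes[r]] = label
        group_of_block[label] = block.group

    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
    annotation = SampleAnnotation(
        pd.DataFrame(
            {"group": [CONTROL] * config.n_per_group + [CASE] * config.n_per_group},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    truth = SyntheticTruth(
        de_genes={genes[i]: int(signs[i]) for i in range(config.n_de)},
        block_membership=truth_blocks,
        group_of_block=group_of_block,
    )
    return matrix, annotation, truth


def generate_null_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """No-signal variant: both groups are draws from the same distribution."""
    null_cfg = replace(config, n_de=0, blocks=())
    return generate_two_group_dataset(null_cfg)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize ground truth as a plain key-value text file."""
    with open(Path(path), "w") as fh:
        for gene, sign in truth.de_genes.items():
            fh.write(f"de\t{gene}\t{sign:+d}\n")
        for gene, label in truth.block_membership.items():
            fh.write(f"block\t{gene}\t{label}\n")
        for label, group in truth.group_of_block.items():
            fh.write(f"block_group\t{label}\t{group}\n")


def read_truth(path) -> SyntheticTruth:
    de: dict[str, int] = {}
    membership: dict[str, str] = {}
    groups: dict[str, str] = {}
    with open(Path(path)) as fh:
        for line in fh:
            kind, key, value = line.rstrip("\n").split("\t")
            if kind == "de":
                de[key] = int(value)
            elif kind == "block":
                membership[key] = value
            elif kind == "block_group":
                groups[key] = value
    return SyntheticTruth(de_genes=de, block_membership=membership, group_of_block=groups)
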