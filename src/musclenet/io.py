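"""Expression matrix, sample annotation, gene-list and gene-set I/O.

The primary on-disk dialect is plain tab-delimited text: a ``gene_id``
corner header, sample IDs across the top and one gene per row, holding
log2-scale intensities (RMA-style output).  GEO series-matrix comment
lines starting with ``!`` are tolerated on read.  Gene sets use the GMT
dialect (set name, description, members, tab-separated).

Three packaged fixtures transcribe the study's printed tables: the
14-sample cohort description, the 96-row differential expression table
(signed linear fold changes, decimal commas normalised to points) and the
100-rank discriminant gene list.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_sets",
    "write_gene_sets",
    "load_fixture_tables",
    "fold_change_to_log2",
    "log2_to_fold_change",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes × samples matrix of log2 intensities.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by unique gene IDs, columns by unique sample IDs,
        all values finite floats.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ParseError("expression matrix must have at least one gene and one sample")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ParseError(f"duplicate gene ID: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise ParseError(f"duplicate sample ID: {dup!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ParseError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ParseError(
                f"non-finite value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"unknown gene IDs: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def select_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)])

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self.data.equals(other.data)


@dataclass(frozen=True)
class SampleAnnotation:
    """Sample → group mapping with optional free covariates.

    Exactly two distinct group labels are required, both non-empty.
    """

    table: pd.DataFrame  # indexed by sample_id, with a 'group' column

    def __post_init__(self) -> None:
        df = self.table
        if "group" not in df.columns:
            raise ParseError("annotation needs a 'group' column")
        if df.index.duplicated().any():
            raise ParseError(f"duplicate sample ID: {df.index[df.index.duplicated()][0]!r}")
        labels = df["group"].unique()
        if len(labels) != 2:
            raise ParseError(f"annotation must define exactly two groups, got {list(labels)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def group_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for g in self.table["group"]:
            if g not in seen:
                seen.append(g)
        return (seen[0], seen[1])

    def samples_in(self, group: str) -> list[str]:
        if group not in self.table["group"].values:
            raise KeyError(f"unknown group label {group!r}")
        return list(self.table.index[self.table["group"] == group])

    def check_covers(self, matrix: ExpressionMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in self.table.index]
        if missing:
            raise ParseError(f"samples missing from annotation: {missing[:5]}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, *, transposed: bool = False) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First column holds gene IDs, header row holds sample IDs (the reverse
    with ``transposed=True``).  Lines beginning with ``!`` (GEO
    series-matrix commentary) are skipped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="!", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse tab-delimited matrix: {exc}") from exc
    if transposed:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    try:
        num = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ParseError(
                    f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
                ) from None
        raise
    try:
        return ExpressionMatrix(num)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix so that :func:`read_expression_matrix` inverts it exactly."""
    path = Path(path)
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_annotation(path) -> SampleAnnotation:
    """Read a two-column (or wider) TSV: sample_id, group, free covariates."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    try:
        return SampleAnnotation(df)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_annotation(annotation: SampleAnnotation, path) -> None:
    df = annotation.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_gene_sets(path) -> dict[str, frozenset[str]]:
    """Read GMT gene sets: name, description, members, tab-separated."""
    sets: dict[str, frozenset[str]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs ≥3 fields, got {len(fields)}")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return sets


def write_gene_sets(sets: Mapping[str, frozenset[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# fold-change conventions
# ---------------------------------------------------------------------------

def fold_change_to_log2(fc: float) -> float:
    """Signed linear fold change → log2 fold change.

    A printed value of −4.82 means 4.82-fold down, i.e. log2FC = −log2(4.82).
    """
    if fc == 0:
        raise ValueError("fold change of 0 is undefined")
    return float(np.sign(fc) * np.log2(abs(fc)))


def log2_to_fold_change(log2fc: float) -> float:
    """log2 fold change → signed linear fold change (|FC| ≥ 1 by construction)."""
    return float(np.sign(log2fc) * 2.0 ** abs(log2fc)) if log2fc != 0 else 1.0


# ---------------------------------------------------------------------------
# packaged fixtures (transcriptions of the study's printed tables)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrintedTables:
    """The three printed tables shipped with the package.

    cohort : 14 biopsy samples (7 control, 7 ALS) with sex, age, site.
    de_genes : 96 differentially expressed probes with raw p and signed
        linear fold change exactly as printed (``p_censored`` marks
        entries printed as an upper bound).
    discriminant : the 100-rank discriminant gene list with
        mitochondrial / muscle-specific / appears-in-DE-list flags; the
        printed table leaves one rank blank and repeats two symbols, and
        the fixture preserves those rows verbatim.
    """

    cohort: pd.DataFrame
    de_genes: pd.DataFrame
    discriminant: pd.DataFrame

    def cohort_annotation(self) -> SampleAnnotation:
        df = self.cohort.set_index("sample_id")
        return SampleAnnotation(df)


def _data_path(name: str) -> Path:
    res = importlib.resources.files("musclenet") / "data" / name
    with importlib.resources.as_file(res) as p:
        if not p.exists():
            raise ParseError(f"packaged fixture missing: {name}")
        return p


def load_fixture_tables() -> PrintedTables:
    """Load the packaged printed-table fixtures."""
    cohort = pd.read_csv(_data_path("table1_cohort.tsv"), sep="\t", dtype={"sample_id": str})
    de = pd.read_csv(_data_path("table2_de_genes.tsv"), sep="\t")
    disc = pd.read_csv(_data_path("table3_discriminant.tsv"), sep="\t")
    if len(cohort) != 14:
        raise ParseError("cohort fixture corrupt: expected 14 samples")
    if sorted(disc["rank"]) != list(range(1, 101)):
        raise ParseError("discriminant fixture corrupt: ranks 1..100 required")
    if (de["fold_change"] == 0).any() or (de["fold_change"].abs() < 2).any():
        raise ParseError("DE fixture corrupt: |FC| ≥ 2 expected for every printed row")
    return PrintedTables(cohort=cohort, de_genes=de, discriminant=disc)
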