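"""Transposed PCA, discriminant component selection and classical MDS.

Here PCA is run with *genes as statistical units and samples as
variables*: the decomposition diagonalizes the samples × samples
covariance of the genes × samples matrix.  Because genes vastly
outnumber samples this direction is far better conditioned than the
usual one, and the first component absorbs the shared gene-abundance
profile of the tissue (typically >97% of total variance); the minor
components carry the between-sample differences of interest.

Two derived quantities drive the downstream analysis:

* *gene scores* — the projection of each gene onto each component;
* *factor loadings* (FL) — the Pearson correlation between each
  sample's expression vector (over genes) and a component's score
  vector, quantifying how strongly each sample weighs on the component.

The discriminant component is the non-leading component whose factor
loadings best separate the two groups, measured by the one-dimensional
Fisher discriminant ratio (squared mean difference over pooled
within-group variance) — the statistic a linear discriminant analysis
reduces to on a single feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from .errors import ConfigurationError
from .io import ExpressionMatrix, SampleAnnotation

__all__ = [
    "PCADecomposition",
    "DiscriminantSelection",
    "transpose_pca",
    "select_discriminant_component",
    "rank_genes_by_score",
    "classical_mds",
]


@dataclass(frozen=True)
class PCADecomposition:
    """Eigenstructure of the samples × samples covariance.

    ``gene_scores`` is genes × components, ``factor_loadings`` is
    samples × components; components are numbered from 1 in order of
    decreasing eigenvalue, each oriented so its largest-|value| gene
    score is positive.
    """

    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    gene_scores: pd.DataFrame
    factor_loadings: pd.DataFrame
    centered: bool

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "eigenvalue": self.eigenvalues,
                "variance_fraction": self.variance_fractions,
            }
        )


@dataclass(frozen=True)
class DiscriminantSelection:
    """Outcome of the per-component group-separation scan.

    ``separations`` holds the Fisher discriminant ratio of each eligible
    component's factor loadings; ``component`` is the maximizer (1-based)
    and ``discriminating`` is False when even the best ratio does not
    exceed the configured floor.
    """

    separations: pd.Series
    component: int
    discriminating: bool


def transpose_pca(
    matrix: ExpressionMatrix, *, center: bool = True, standardize: bool = False
) -> PCADecomposition:
    """PCA of the expression matrix with genes as observations.

    ``center`` removes each sample's mean over genes (per-variable
    centering); the shared gene-abundance axis still dominates the first
    component because it varies across genes, not samples.
    ``standardize`` additionally scales each sample to unit variance
    (correlation PCA); the default is covariance PCA.
    """
    if matrix.n_genes < 2 or matrix.n_samples < 2:
        raise ConfigurationError("transpose_pca needs at least 2 genes and 2 samples")
    x = matrix.values.copy()
    if center:
        x -= x.mean(axis=0, keepdims=True)
    if standardize:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ConfigurationError("cannot standardize a constant sample column")
        x /= sd
    if not np.any(x != x[0, 0]) or np.allclose(x.var(axis=0), 0):
        raise ConfigurationError("degenerate matrix: no variance across genes")

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    g = matrix.n_genes
    eig = s**2 / (g - 1)
    fractions = eig / eig.sum()
    scores = u * s  # genes × components

    # deterministic sign: largest-|score| gene positive on every component
    for k in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, k])))
        if scores[i, k] < 0:
            scores[:, k] = -scores[:, k]

    comp_names = [f"PC{k+1}" for k in range(scores.shape[1])]
    gene_scores = pd.DataFrame(scores, index=matrix.data.index, columns=comp_names)

    # factor loadings: Pearson r between each original sample column and
    # each score vector (zero where a component carries no variance)
    cols = matrix.values - matrix.values.mean(axis=0, keepdims=True)
    col_norm = np.linalg.norm(cols, axis=0)
    sc = scores - scores.mean(axis=0, keepdims=True)
    sc_norm = np.linalg.norm(sc, axis=0)
    tol = 1e-12 * max(col_norm.max(), sc_norm.max(), 1.0)
    safe_cols = np.where(col_norm > tol, col_norm, 1.0)
    safe_sc = np.where(sc_norm > tol, sc_norm, 1.0)
    fl = (cols / safe_cols).T @ (sc / safe_sc)
    fl[:, sc_norm <= tol] = 0.0
    fl[col_norm <= tol, :] = 0.0
    fl = np.clip(fl, -1.0, 1.0)
    factor_loadings = pd.DataFrame(fl, index=matrix.data.columns, columns=comp_names)

    return PCADecomposition(
        eigenvalues=eig,
        variance_fractions=fractions,
        gene_scores=gene_scores,
        factor_loadings=factor_loadings,
        centered=center,
    )


def _fisher_ratio(values: np.ndarray, in_a: np.ndarray) -> float:
    a, b = values[in_a], values[~in_a]
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    pooled = ((len(a) - 1) * va + (len(b) - 1) * vb) / (len(a) + len(b) - 2)
    diff2 = (a.mean() - b.mean()) ** 2
    if pooled == 0:
        return np.inf if diff2 > 0 else 0.0
    return float(diff2 / pooled)


def select_discriminant_component(
    decomp: PCADecomposition,
    annotation: SampleAnnotation,
    *,
    exclude_first: bool = True,
    min_separation: float = 0.0,
) -> DiscriminantSelection:
    """Pick the component whose factor loadings best separate the groups.

    The first component — the tissue-profile axis — is excluded by
    default.  ``min_separation`` is the floor below which even the best
    component is flagged as non-discriminating.
    """
    fl = decomp.factor_loadings
    missing = [s for s in fl.index if s not in annotation.table.index]
    if missing:
        raise ConfigurationError(f"samples not annotated: {missing[:5]}")
    label_a = annotation.group_labels[0]
    groups = annotation.table.loc[fl.index, "group"].to_numpy()
    in_a = groups == label_a
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ConfigurationError("each group needs at least 2 samples")

    start = 1 if exclude_first else 0
    if decomp.n_components <= start:
        raise ConfigurationError("no eligible components to scan")
    ratios = {
        k + 1: _fisher_ratio(fl.iloc[:, k].to_numpy(), in_a)
        for k in range(start, decomp.n_components)
    }
    separations = pd.Series(ratios, name="fisher_ratio")
    component = int(separations.idxmax())
    return DiscriminantSelection(
        separations=separations,
        component=component,
        discriminating=bool(separations.loc[component] > min_separation),
    )


def rank_genes_by_score(
    decomp: PCADecomposition, component: int, k: int = 100
) -> pd.DataFrame:
    """Top-``k`` genes by |score| on a component (1-based index).

    Ties are broken by gene ID lexicographic order; columns are
    ``rank``, ``gene_id``, ``score``.
    """
    if k <= 0:
        raise ConfigurationError("k must be ≥ 1")
    if not 1 <= component <= decomp.n_components:
        raise ConfigurationError(
            f"component must be in 1..{decomp.n_components}, got {component}"
        )
    col = decomp.gene_scores.iloc[:, component - 1]
    order = sorted(col.index, key=lambda gid: (-abs(col[gid]), str(gid)))
    top = order[: min(k, len(order))]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(top) + 1),
            "gene_id": top,
            "score": [col[g] for g in top],
        }
    )


def classical_mds(matrix: ExpressionMatrix, n_dims: int = 3) -> pd.DataFrame:
    """Classical scaling of the samples' pairwise Euclidean distances.

    Equivalent, up to sign and rotation, to the leading principal
    coordinates of the sample cloud; returns a samples × ``n_dims``
    coordinate table.
    """
    n = matrix.n_samples
    if n_dims < 1:
        raise ConfigurationError("n_dims must be ≥ 1")
    if n_dims >= n:
        raise ConfigurationError(f"n_dims must be < number of samples ({n})")
    dm = DistanceMatrix(squareform(pdist(matrix.values.T)), ids=matrix.sample_ids)
    ord_res = pcoa(dm, number_of_dimensions=n_dims)
    coords = ord_res.samples.iloc[:, :n_dims].copy()
    coords.columns = [f"dim{i+1}" for i in range(n_dims)]
    coords.index = pd.Index(matrix.sample_ids, name="sample_id")
    return coords
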