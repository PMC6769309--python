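"""Correlation-dissimilarity point clouds.

Samples (or genes) become points in a finite pseudo-metric space with
pairwise dissimilarity ``1 - r``, where ``r`` is the Pearson
correlation between the two expression vectors.  Perfectly correlated
points are at distance 0, perfectly anti-correlated ones at distance 2.
Note that ``1 - r`` need not satisfy the triangle inequality; the
persistence machinery only requires a symmetric dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConstantVectorError, ValidationError
from .io import ExpressionMatrix

__all__ = ["DissimilarityMatrix", "pearson_dissimilarity", "PearsonDissimilarity",
           "drop_constant_genes"]


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarity matrix with zero diagonal over labelled points.

    ``eps_max`` (the maximum pairwise dissimilarity) is the filtration
    truncation value used by the persistence computations.
    """

    labels: tuple[str, ...]
    d: np.ndarray
    metric_name: str = "one_minus_pearson"

    def __post_init__(self) -> None:
        self.labels = tuple(str(x) for x in self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.isfinite(self.d).all():
            raise ValidationError("dissimilarity matrix contains non-finite entries")
        if not np.array_equal(self.d, self.d.T):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if np.any(np.diagonal(self.d) != 0.0):
            raise ValidationError("dissimilarity matrix diagonal must be zero")

    @property
    def n_points(self) -> int:
        return len(self.labels)

    @property
    def eps_max(self) -> float:
        return float(self.d.max(initial=0.0))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        return path


def _one_minus_pearson(vectors: np.ndarray) -> np.ndarray:
    """1 - Pearson over the rows of ``vectors`` (points x coordinates)."""
    n, p = vectors.shape
    if p < 2:
        raise ValidationError(
            "Pearson correlation needs >= 2 coordinates per point "
            f"(got {p}); cannot build a point cloud from a single column"
        )
    centered = vectors - vectors.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    corr = (centered @ centered.T) / np.outer(norms, norms)
    d = 1.0 - corr
    # exact symmetry and range: compute each unordered pair once
    d = np.triu(d, k=1)
    d = np.clip(d, 0.0, 2.0)
    d = d + d.T
    return d


def pearson_dissimilarity(expr: ExpressionMatrix, axis: str = "samples") -> DissimilarityMatrix:
    """Build the ``1 - r`` dissimilarity matrix over samples or genes.

    ``axis="samples"`` correlates sample columns across all genes (the
    sample-level point cloud); ``axis="genes"`` correlates gene rows
    across all samples of the matrix (the gene-level cloud, typically
    computed per group).

    Raises
    ------
    ConstantVectorError
        If any vector has zero variance: its correlation is undefined.
        Use the explicit constant-gene pre-filter upstream rather than
        silently dropping rows, so both groups keep identical gene
        universes.
    """
    if axis == "samples":
        vectors = expr.values.T
        labels = expr.sample_ids
        what = "sample"
    elif axis == "genes":
        vectors = expr.values
        labels = expr.gene_ids
        what = "gene"
    else:
        raise ValidationError(f"axis must be 'samples' or 'genes', got {axis!r}")
    variances = vectors.var(axis=1)
    bad = np.nonzero(variances == 0.0)[0]
    if bad.size:
        raise ConstantVectorError(
            f"{what} {labels[bad[0]]!r} has zero variance; "
            "its Pearson correlation is undefined"
        )
    return DissimilarityMatrix(labels, _one_minus_pearson(np.asarray(vectors, float)))


def drop_constant_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose expression is constant across ALL samples.

    Applied before group splitting so both groups keep the same gene
    universe.  Note a gene can still be constant within one group.
    """
    keep = [g for g, row in zip(expr.gene_ids, expr.values) if row.var() > 0.0]
    return expr.subset_genes(keep)


class PearsonDissimilarity(BaseEstimator, TransformerMixin):
    """Transformer form of :func:`pearson_dissimilarity`.

    ``transform`` accepts an :class:`~topohet.io.ExpressionMatrix` (the
    ``axis`` parameter selects the point set) or a plain 2-D array whose
    rows are points, and returns the square dissimilarity ndarray.
    """

    def __init__(self, axis: str = "samples"):
        self.axis = axis

    def fit(self, X, y=None):  # stateless
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, ExpressionMatrix):
            return pearson_dissimilarity(X, axis=self.axis).d
        X = np.asarray(X, dtype=float)
        if np.any(X.var(axis=1) == 0.0):
            i = int(np.nonzero(X.var(axis=1) == 0.0)[0][0])
            raise ConstantVectorError(f"row {i} has zero variance")
        return _one_minus_pearson(X)
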