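"""Mahalanobis-distance heterogeneity analysis (the comparison method).

Each case sample's expression vector x_i is scored by its Mahalanobis
distance from the control centroid,

    MD(x_i, x_c) = sqrt((x_i - x_c)^T  Psi^+  (x_i - x_c)),

where x_c is the per-gene mean over controls and Psi^+ the
Moore-Penrose pseudoinverse of the sample covariance (denominator
n - 1) of the controls.  In the transcriptomic regime genes far exceed
samples, the covariance is singular by construction and the
pseudoinverse measures distance within the controls' sample span.  The
group-dispersion statistic is SSMD, the sum of squared MDs over case
samples, tested one-sided (dispersion can only be "too large") against
a label-permutation null in which the model is refit on each permuted
control half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .errors import AlignmentError, ValidationError
from .io import ExpressionMatrix, GeneSetCollection, SampleMetadata
from .permutation import GeneSetScanEntry, GeneSetScanResult, _as_expr_meta, _case_control

logger = logging.getLogger(__name__)

__all__ = [
    "MahalanobisModel",
    "SSMDResult",
    "fit_model",
    "mahalanobis_distance",
    "ssmd_label_permutation_test",
    "ssmd_geneset_test",
    "ControlMahalanobis",
    "SSMDPermutationTest",
    "SSMDGeneSetScan",
]


@dataclass
class MahalanobisModel:
    """Control centroid plus pseudo-inverted control covariance."""

    control_mean: np.ndarray
    cov_pinv: np.ndarray
    rank: int
    rank_tolerance: float
    gene_ids: tuple[str, ...]


def _pinv_psd(cov: np.ndarray, rank_tolerance: float | None) -> tuple[np.ndarray, int, float]:
    """Moore-Penrose pseudoinverse of a symmetric PSD matrix via SVD.

    Singular values below ``tol = rank_tolerance * s_max`` (default
    ``eps * dim``) are treated as zero, the conventional cutoff.
    """
    u, s, vt = np.linalg.svd(cov, hermitian=True)
    s_max = s[0] if s.size else 0.0
    rel = rank_tolerance if rank_tolerance is not None \
        else np.finfo(float).eps * max(cov.shape)
    tol = rel * s_max
    keep = s > tol
    inv = np.zeros_like(s)
    inv[keep] = 1.0 / s[keep]
    pinv = (vt.T * inv) @ vt
    pinv = (pinv + pinv.T) / 2.0  # exact symmetry
    return pinv, int(keep.sum()), rel


def fit_model(controls: ExpressionMatrix,
              rank_tolerance: float | None = None) -> MahalanobisModel:
    """Fit centroid and covariance pseudoinverse on the control group."""
    if controls.n_samples < 2:
        raise ValidationError(
            "covariance estimation needs >= 2 control samples "
            f"(got {controls.n_samples})"
        )
    X = controls.values.T  # samples x genes
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    pinv, rank, rel = _pinv_psd(cov, rank_tolerance)
    if rank < cov.shape[0]:
        logger.info("control covariance is rank-deficient: rank %d of %d "
                    "(genes >> samples regime); using the pseudoinverse",
                    rank, cov.shape[0])
    return MahalanobisModel(mean, pinv, rank, rel, controls.gene_ids)


def mahalanobis_distance(model: MahalanobisModel, x: np.ndarray) -> float:
    """MD of one expression vector from the control centroid.

    The quadratic form is clipped at zero before the square root to
    guard against -1e-18-scale rounding artifacts.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != model.control_mean.shape:
        raise AlignmentError(
            f"vector length {x.shape} does not match model genes "
            f"{model.control_mean.shape}"
        )
    diff = x - model.control_mean
    q = float(diff @ model.cov_pinv @ diff)
    return float(np.sqrt(max(q, 0.0)))


def _ssmd(cases: ExpressionMatrix, controls: ExpressionMatrix,
          rank_tolerance: float | None) -> tuple[float, dict[str, float]]:
    model = fit_model(controls, rank_tolerance)
    per_sample = {s: mahalanobis_distance(model, cases.values[:, j])
                  for j, s in enumerate(cases.sample_ids)}
    return float(sum(v * v for v in per_sample.values())), per_sample


@dataclass
class SSMDResult:
    ssmd_observed: float
    per_sample_md: dict[str, float]
    null_values: np.ndarray | None
    fdr: float | None
    n_perm: int
    seed: int


def ssmd_label_permutation_test(expr: ExpressionMatrix, meta: SampleMetadata,
                                n_perm: int = 1000, seed: int = 0,
                                rank_tolerance: float | None = None,
                                case_label: str | None = None) -> SSMDResult:
    """SSMD of the case group against a refitted label-permutation null.

    Each permutation re-splits the pooled samples into two equal
    halves, refits centroid and covariance pseudoinverse on the
    permuted controls, and recomputes SSMD of the permuted cases.
    FDR = proportion of null values >= observed (one-sided: SSMD is a
    non-negative dispersion excess).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    expr_case, expr_control = _case_control(expr, meta, case_label)
    observed, per_sample = _ssmd(expr_case, expr_control, rank_tolerance)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pooled = list(expr.sample_ids)
    n_half = expr_case.n_samples
    null = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(len(pooled))
        cases = expr.subset_samples([pooled[i] for i in order[:n_half]])
        controls = expr.subset_samples([pooled[i] for i in order[n_half:]])
        null[b], _ = _ssmd(cases, controls, rank_tolerance)
    fdr = float(np.mean(null >= observed))
    return SSMDResult(observed, per_sample, null, fdr, n_perm, seed)


def ssmd_geneset_test(expr: ExpressionMatrix, meta: SampleMetadata,
                      sets: GeneSetCollection, n_random: int = 100,
                      seed: int = 0, rank_tolerance: float | None = None,
                      case_label: str | None = None) -> GeneSetScanResult:
    """Per-set SSMD versus size-matched random gene sets.

    The model is refit on the control samples restricted to each gene
    subset.  Sets with fewer than 2 expressed genes are skipped.
    FDR = proportion of random-set SSMD values >= the observed one.
    """
    if n_random < 1:
        raise ValidationError("n_random must be >= 1")
    expr_case, expr_control = _case_control(expr, meta, case_label)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = list(expr.gene_ids)
    present = set(universe)
    per_set: dict[str, GeneSetScanEntry] = {}
    skipped: list[str] = []
    for gs in sets:
        genes = [g for g in gs.genes if g in present]
        if len(genes) < 2:
            logger.warning("gene set %r skipped: only %d expressed genes (< 2)",
                           gs.name, len(genes))
            skipped.append(gs.name)
            continue
        observed, _ = _ssmd(expr_case.subset_genes(genes),
                            expr_control.subset_genes(genes), rank_tolerance)
        null = np.empty(n_random)
        for b in range(n_random):
            pick = rng.choice(len(universe), size=len(genes), replace=False)
            rand = [universe[i] for i in np.sort(pick)]
            null[b], _ = _ssmd(expr_case.subset_genes(rand),
                               expr_control.subset_genes(rand), rank_tolerance)
        per_set[gs.name] = GeneSetScanEntry(len(genes), observed, null,
                                            float(np.mean(null >= observed)))
    return GeneSetScanResult(per_set, n_random, seed, tuple(skipped))


class ControlMahalanobis(BaseEstimator):
    """Sklearn-style Mahalanobis scorer fit on control samples.

    ``fit(X)`` takes controls as a samples x genes array or an
    :class:`~topohet.io.ExpressionMatrix`; ``mahalanobis(X)`` (alias
    ``transform``) returns per-sample distances from the control
    centroid.
    """

    def __init__(self, rank_tolerance: float | None = None):
        self.rank_tolerance = rank_tolerance

    def fit(self, X, y=None):
        if not isinstance(X, ExpressionMatrix):
            X = np.asarray(X, dtype=float)
            X = ExpressionMatrix(tuple(f"g{j}" for j in range(X.shape[1])),
                                 tuple(f"s{i}" for i in range(X.shape[0])), X.T)
        model = fit_model(X, self.rank_tolerance)
        self.model_ = model
        self.mean_ = model.control_mean
        self.cov_pinv_ = model.cov_pinv
        self.rank_ = model.rank
        return self

    def mahalanobis(self, X) -> np.ndarray:
        if isinstance(X, ExpressionMatrix):
            X = X.values.T
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([mahalanobis_distance(self.model_, row) for row in X])

    def transform(self, X) -> np.ndarray:
        return self.mahalanobis(X)


class SSMDGeneSetScan(BaseEstimator):
    """Sklearn-style estimator wrapping :func:`ssmd_geneset_test`."""

    def __init__(self, n_random: int = 100, rank_tolerance: float | None = None,
                 case_label: str | None = None, random_state: int = 0):
        self.n_random = n_random
        self.rank_tolerance = rank_tolerance
        self.case_label = case_label
        self.random_state = random_state

    def fit(self, X, y, gene_sets: GeneSetCollection = None):
        if gene_sets is None:
            raise ValidationError("gene_sets is required")
        from .permutation import filter_genesets

        expr, meta = _as_expr_meta(X, y)
        result = ssmd_geneset_test(expr, meta, filter_genesets(gene_sets, expr),
                                   n_random=self.n_random,
                                   seed=self.random_state,
                                   rank_tolerance=self.rank_tolerance,
                                   case_label=self.case_label)
        self.result_ = result
        self.fdr_ = {name: e.fdr for name, e in result.per_set.items()}
        return self


class SSMDPermutationTest(BaseEstimator):
    """Sklearn-style estimator wrapping :func:`ssmd_label_permutation_test`."""

    def __init__(self, n_perm: int = 1000, rank_tolerance: float | None = None,
                 case_label: str | None = None, random_state: int = 0):
        self.n_perm = n_perm
        self.rank_tolerance = rank_tolerance
        self.case_label = case_label
        self.random_state = random_state

    def fit(self, X, y):
        expr, meta = _as_expr_meta(X, y)
        result = ssmd_label_permutation_test(expr, meta, n_perm=self.n_perm,
                                             seed=self.random_state,
                                             rank_tolerance=self.rank_tolerance,
                                             case_label=self.case_label)
        self.result_ = result
        self.ssmd_ = result.ssmd_observed
        self.null_values_ = result.null_values
        self.fdr_ = result.fdr
        return self
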