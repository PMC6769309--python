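"""Group-difference statistics and their label-permutation nulls.

The inferential machinery: for two equal-size sample groups, compute a
topological invariant (SDT0 or the Euler characteristic chi) of each
group's correlation-dissimilarity point cloud and take the difference

    D = invariant(case) - invariant(control).

Significance is assessed by repeatedly re-partitioning the pooled
samples into two random equal halves and recomputing D from scratch
(distances, persistence, landmarks included).  Following the source
terminology this empirical tail proportion is reported as an "FDR",
although operationally it is a permutation p-value:

    FDR = #{permutations with a more extreme D} / n_perm.

"More extreme" defaults to the two-sided rule |D_perm| >= |D_obs|;
``sided="greater"`` restores the one-sided variant.

The gene-set scan asks the complementary question: restricted to one
gene set's genes, is D more extreme than for random size-matched gene
sets drawn from the expressed universe?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .distances import pearson_dissimilarity
from .errors import GroupContractError, ValidationError
from .invariants import summarize
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleMetadata,
    split_by_group,
)
from .persistence import (
    lazy_witness_persistence,
    rips_persistence,
    select_landmarks,
    zero_dim_persistence,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroupStatistic",
    "PermutationResult",
    "GeneSetScanResult",
    "group_statistic_difference",
    "label_permutation_test",
    "filter_genesets",
    "geneset_topology_scan",
    "TopologyPermutationTest",
    "GeneSetTopologyScan",
]

_MIN_GENESET_SIZE = 3  # Pearson needs >= 3 coordinates to be non-degenerate


@dataclass(frozen=True)
class GroupStatistic:
    """Which invariant, on which point cloud.

    kind : ``"sdt0"`` (sum of dimension-0 death times) or ``"euler"``
        (chi = SL0 - SL1 + SL2).
    level : ``"sample"`` (Vietoris-Rips on the sample cloud) or
        ``"gene"`` (lazy-witness on the gene cloud over landmarks).
    max_dim : homology cap; defaults to 2 at sample level and 3 at gene
        level when left as None.
    landmark_size, landmark_method, nu : gene-level only.
    """

    kind: str = "sdt0"
    level: str = "sample"
    max_dim: int | None = None
    landmark_size: int = 20
    landmark_method: str = "maxmin"
    nu: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("sdt0", "euler"):
            raise ValidationError(f"kind must be 'sdt0' or 'euler', got {self.kind!r}")
        if self.level not in ("sample", "gene"):
            raise ValidationError(f"level must be 'sample' or 'gene', got {self.level!r}")

    @property
    def effective_max_dim(self) -> int:
        if self.max_dim is not None:
            return self.max_dim
        return 2 if self.level == "sample" else 3


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    fdr: float
    n_perm: int
    seed: int
    statistic: GroupStatistic
    sided: str = "two"


@dataclass
class GeneSetScanEntry:
    set_size_used: int
    observed_d: float
    null_d: np.ndarray
    fdr: float


@dataclass
class GeneSetScanResult:
    per_set: dict[str, GeneSetScanEntry]
    n_random_sets: int
    seed: int
    skipped: tuple[str, ...] = ()

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("set_name\tset_size_used\tobserved_D\tfdr\n")
            for name, e in self.per_set.items():
                fh.write(f"{name}\t{e.set_size_used}\t{e.observed_d!r}\t{e.fdr!r}\n")
        return path


def group_invariant(expr: ExpressionMatrix, stat: GroupStatistic,
                    landmark_seed: int = 0) -> float:
    """The chosen invariant of one group's point cloud.

    Sample-level SDT0 uses the exact union-find fast path (identical to
    full Rips dimension 0); everything else goes through the full
    reduction.  Gene-level clouds get their own landmark selection per
    call, since landmarks depend on the group's distance matrix.
    """
    if stat.level == "sample":
        dmat = pearson_dissimilarity(expr, axis="samples")
        if stat.kind == "sdt0":
            diagram = zero_dim_persistence(dmat)
        else:
            diagram = rips_persistence(dmat, max_dim=stat.effective_max_dim)
    else:
        dmat = pearson_dissimilarity(expr, axis="genes")
        k = min(stat.landmark_size, dmat.n_points)
        lm = select_landmarks(dmat, k, method=stat.landmark_method,
                              seed=landmark_seed, nu=stat.nu)
        diagram = lazy_witness_persistence(dmat, lm, max_dim=stat.effective_max_dim)
    summary = summarize(diagram)
    return summary.sdt0 if stat.kind == "sdt0" else summary.chi


def group_statistic_difference(expr_case: ExpressionMatrix,
                               expr_control: ExpressionMatrix,
                               stat: GroupStatistic,
                               landmark_seeds: tuple[int, int] = (0, 1)) -> float:
    """D = invariant(case) - invariant(control).

    Both matrices must share the gene universe and have equal sample
    counts (dimension-0 topology depends on the number of points).
    """
    if expr_case.gene_ids != expr_control.gene_ids:
        raise GroupContractError("the two groups must share an identical gene universe")
    if expr_case.n_samples != expr_control.n_samples:
        raise GroupContractError(
            f"groups must have equal sample counts "
            f"(got {expr_case.n_samples} vs {expr_control.n_samples})"
        )
    return (group_invariant(expr_case, stat, landmark_seeds[0])
            - group_invariant(expr_control, stat, landmark_seeds[1]))


def _fdr(observed: float, null: np.ndarray, sided: str) -> float:
    if sided == "two":
        return float(np.mean(np.abs(null) >= abs(observed)))
    if sided == "greater":
        return float(np.mean(null >= observed))
    raise ValidationError(f"sided must be 'two' or 'greater', got {sided!r}")


def _case_control(expr: ExpressionMatrix, meta: SampleMetadata,
                  case_label: str | None) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    first, second = split_by_group(expr, meta)
    g1, g2 = meta.groups
    if case_label is None:
        case_label = g2
    if case_label == g2:
        return second, first
    if case_label == g1:
        return first, second
    raise ValidationError(f"case_label {case_label!r} is not a group label {meta.groups}")


def label_permutation_test(expr: ExpressionMatrix, meta: SampleMetadata,
                           stat: GroupStatistic, n_perm: int = 1000,
                           seed: int = 0, sided: str = "two",
                           case_label: str | None = None) -> PermutationResult:
    """Permutation null for D by random re-partition of the pooled samples.

    Each permutation shuffles all samples and splits them into two
    equal halves (group sizes preserved); distances, landmarks and
    persistence are recomputed from scratch for both halves.  The case
    group defaults to the second label in metadata order.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    expr_case, expr_control = _case_control(expr, meta, case_label)
    n_half = expr_case.n_samples

    ss = np.random.SeedSequence(seed)
    shuffle_child, landmark_child = ss.spawn(2)
    rng = np.random.default_rng(shuffle_child)
    landmark_seeds = landmark_child.generate_state(2 * (n_perm + 1)) % (2 ** 31)

    observed = group_statistic_difference(
        expr_case, expr_control, stat,
        landmark_seeds=(int(landmark_seeds[0]), int(landmark_seeds[1])))

    pooled = list(expr.sample_ids)
    null = np.empty(n_perm)
    for b in range(n_perm):
        order = rng.permutation(len(pooled))
        half_a = [pooled[i] for i in order[:n_half]]
        half_b = [pooled[i] for i in order[n_half:]]
        null[b] = group_statistic_difference(
            expr.subset_samples(half_a), expr.subset_samples(half_b), stat,
            landmark_seeds=(int(landmark_seeds[2 * b + 2]),
                            int(landmark_seeds[2 * b + 3])))
    return PermutationResult(observed, null, _fdr(observed, null, sided),
                             n_perm, seed, stat, sided)


def filter_genesets(sets: GeneSetCollection, expr: ExpressionMatrix
                    ) -> GeneSetCollection:
    """Keep sets with at least half their genes in the expressed universe.

    Retained sets are intersected with ``expr``'s genes (kept in matrix
    order), so downstream set sizes refer to expressed members only.
    """
    universe = set(expr.gene_ids)
    kept: dict[str, GeneSet] = {}
    for gs in sets:
        members = set(gs.genes)
        present = [g for g in expr.gene_ids if g in members]
        if 2 * len(present) >= len(gs.genes) and present:
            kept[gs.name] = GeneSet(gs.name, gs.description, tuple(present))
    return GeneSetCollection(kept)


def geneset_topology_scan(expr: ExpressionMatrix, meta: SampleMetadata,
                          sets: GeneSetCollection, stat: GroupStatistic,
                          n_random: int = 100, seed: int = 0,
                          sided: str = "two",
                          case_label: str | None = None) -> GeneSetScanResult:
    """Per-set D versus size-matched random gene sets.

    For each (pre-filtered) set, D is computed on the sample cloud
    restricted to the set's expressed genes, and compared against
    ``n_random`` gene sets of the same size drawn uniformly without
    replacement from the full expressed universe.  Sets with fewer than
    3 expressed genes are skipped with a warning.
    """
    if n_random < 1:
        raise ValidationError("n_random must be >= 1")
    if stat.level != "sample":
        raise ValidationError("gene-set scans are computed on sample-level clouds")
    expr_case, expr_control = _case_control(expr, meta, case_label)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = list(expr.gene_ids)
    present = set(universe)

    per_set: dict[str, GeneSetScanEntry] = {}
    skipped: list[str] = []
    for gs in sets:
        genes = [g for g in gs.genes if g in present]
        if len(genes) < _MIN_GENESET_SIZE:
            logger.warning("gene set %r skipped: only %d expressed genes (< %d)",
                           gs.name, len(genes), _MIN_GENESET_SIZE)
            skipped.append(gs.name)
            continue
        observed = group_statistic_difference(
            expr_case.subset_genes(genes), expr_control.subset_genes(genes), stat)
        null = np.empty(n_random)
        for b in range(n_random):
            pick = rng.choice(len(universe), size=len(genes), replace=False)
            rand_genes = [universe[i] for i in np.sort(pick)]
            null[b] = group_statistic_difference(
                expr_case.subset_genes(rand_genes),
                expr_control.subset_genes(rand_genes), stat)
        per_set[gs.name] = GeneSetScanEntry(len(genes), observed, null,
                                            _fdr(observed, null, sided))
    return GeneSetScanResult(per_set, n_random, seed, tuple(skipped))


def _as_expr_meta(X, y) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Adapt (ExpressionMatrix, SampleMetadata) or (array, labels) inputs."""
    if isinstance(X, ExpressionMatrix):
        if not isinstance(y, SampleMetadata):
            y = SampleMetadata({s: str(g) for s, g in zip(X.sample_ids, y)})
        return X, y
    X = np.asarray(X, dtype=float)  # sklearn convention: samples x genes
    sample_ids = tuple(f"s{i}" for i in range(X.shape[0]))
    gene_ids = tuple(f"g{j}" for j in range(X.shape[1]))
    expr = ExpressionMatrix(gene_ids, sample_ids, X.T)
    meta = SampleMetadata({s: str(g) for s, g in zip(sample_ids, np.asarray(y))})
    return expr, meta


class TopologyPermutationTest(BaseEstimator):
    """Sklearn-style estimator wrapping :func:`label_permutation_test`.

    ``fit(X, y)`` accepts either an :class:`~topohet.io.ExpressionMatrix`
    with a :class:`~topohet.io.SampleMetadata` (or label sequence), or a
    plain samples x genes array with a two-group label vector.

    Attributes (after fit)
    ----------------------
    observed_ : float — D on the true labels.
    null_values_ : ndarray — permutation null sample of D.
    fdr_ : float — proportion of more extreme permutation values.
    """

    def __init__(self, kind: str = "sdt0", level: str = "sample",
                 max_dim: int | None = None, landmark_size: int = 20,
                 landmark_method: str = "maxmin", nu: int = 1,
                 n_perm: int = 1000, sided: str = "two",
                 case_label: str | None = None, random_state: int = 0):
        self.kind = kind
        self.level = level
        self.max_dim = max_dim
        self.landmark_size = landmark_size
        self.landmark_method = landmark_method
        self.nu = nu
        self.n_perm = n_perm
        self.sided = sided
        self.case_label = case_label
        self.random_state = random_state

    def _statistic(self) -> GroupStatistic:
        return GroupStatistic(self.kind, self.level, self.max_dim,
                              self.landmark_size, self.landmark_method, self.nu)

    def fit(self, X, y):
        expr, meta = _as_expr_meta(X, y)
        result = label_permutation_test(expr, meta, self._statistic(),
                                        n_perm=self.n_perm,
                                        seed=self.random_state,
                                        sided=self.sided,
                                        case_label=self.case_label)
        self.result_ = result
        self.observed_ = result.observed
        self.null_values_ = result.null_values
        self.fdr_ = result.fdr
        return self


class GeneSetTopologyScan(BaseEstimator):
    """Sklearn-style estimator wrapping :func:`geneset_topology_scan`."""

    def __init__(self, kind: str = "sdt0", n_random: int = 100,
                 sided: str = "two", case_label: str | None = None,
                 random_state: int = 0):
        self.kind = kind
        self.n_random = n_random
        self.sided = sided
        self.case_label = case_label
        self.random_state = random_state

    def fit(self, X, y, gene_sets: GeneSetCollection = None):
        if gene_sets is None:
            raise ValidationError("gene_sets is required")
        expr, meta = _as_expr_meta(X, y)
        filtered = filter_genesets(gene_sets, expr)
        result = geneset_topology_scan(expr, meta, filtered,
                                       GroupStatistic(self.kind, "sample"),
                                       n_random=self.n_random,
                                       seed=self.random_state,
                                       sided=self.sided,
                                       case_label=self.case_label)
        self.result_ = result
        self.fdr_ = {name: e.fdr for name, e in result.per_set.items()}
        return self
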