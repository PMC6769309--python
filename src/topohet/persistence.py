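"""Persistent homology with Z/2 coefficients over dissimilarity matrices.

Three computation paths are provided:

* :func:`rips_persistence` — full Vietoris-Rips filtration with standard
  boundary-matrix column reduction over Z/2;
* :func:`zero_dim_persistence` — exact dimension-0 diagram via
  Kruskal/union-find (the finite death times are exactly the minimum
  spanning tree edge weights), identical to the Rips dimension-0 output
  but usable on clouds far too large for full enumeration;
* :func:`lazy_witness_persistence` — sparse approximation on a landmark
  subset for large (gene-level) clouds.

Filtrations are truncated at ``eps_max`` (the maximum pairwise
dissimilarity).  Classes still alive there are *essential*; essential
classes are excluded from the SL/SBT/SDT sums downstream (a connected
cloud always has exactly one essential component, so group differences
are unaffected).  Pairs with zero persistence (death == birth) are
dropped from diagrams — they contribute nothing to any invariant — but
a dimension-0 conservation check (finite + essential == number of
points) is asserted before dropping.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .distances import DissimilarityMatrix
from .errors import CapacityError, ValidationError

__all__ = [
    "PersistencePair",
    "PersistenceDiagram",
    "LandmarkSet",
    "rips_persistence",
    "zero_dim_persistence",
    "select_landmarks",
    "lazy_witness_persistence",
    "RipsPersistence",
    "LazyWitnessPersistence",
]

DEFAULT_SIMPLEX_CEILING = 10_000_000


@dataclass(frozen=True, order=True)
class PersistencePair:
    """One cycle: homology dimension, birth and death filtration values.

    ``death == math.inf`` marks an essential class (alive at eps_max).
    """

    dim: int
    birth: float
    death: float

    @property
    def essential(self) -> bool:
        return math.isinf(self.death)

    @property
    def length(self) -> float:
        return self.death - self.birth


@dataclass
class PersistenceDiagram:
    """Multiset of persistence pairs, canonically sorted by (dim, birth, death)."""

    pairs: tuple[PersistencePair, ...]
    max_dim: int
    eps_max: float

    def __post_init__(self) -> None:
        self.pairs = tuple(sorted(self.pairs))

    def finite(self, dim: int | None = None) -> tuple[PersistencePair, ...]:
        return tuple(p for p in self.pairs if not p.essential
                     and (dim is None or p.dim == dim))

    def essential(self, dim: int | None = None) -> tuple[PersistencePair, ...]:
        return tuple(p for p in self.pairs if p.essential
                     and (dim is None or p.dim == dim))

    def to_tsv(self, path: str | Path) -> Path:
        """Write as TSV (dimension, birth, death); essential death -> 'inf'."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write("dimension\tbirth\tdeath\n")
            for p in self.pairs:
                death = "inf" if p.essential else repr(float(p.death))
                fh.write(f"{p.dim}\t{float(p.birth)!r}\t{death}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, max_dim: int | None = None,
                 eps_max: float = float("nan")) -> "PersistenceDiagram":
        pairs = []
        with Path(path).open() as fh:
            next(fh)
            for line in fh:
                d, b, de = line.rstrip("\n").split("\t")
                pairs.append(PersistencePair(int(d), float(b), float(de)))
        if max_dim is None:
            max_dim = max((p.dim for p in pairs), default=0)
        return cls(tuple(pairs), max_dim, eps_max)


def _as_matrix(d: DissimilarityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(d, DissimilarityMatrix):
        return d.d
    m = np.asarray(d, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("expected a square dissimilarity matrix")
    if not np.isfinite(m).all():
        raise ValidationError("dissimilarity matrix contains non-finite entries")
    if not np.array_equal(m, m.T) or np.any(np.diagonal(m) != 0.0):
        raise ValidationError("matrix must be symmetric with zero diagonal")
    return m


def _simplex_count(n: int, top_dim: int) -> int:
    return sum(math.comb(n, k + 1) for k in range(top_dim + 1))


def _reduce_filtration(simplices: list[tuple[float, int, tuple[int, ...]]],
                       max_dim: int, n_points: int,
                       eps_max: float) -> PersistenceDiagram:
    """Z/2 column reduction of an ordered filtration.

    ``simplices`` must already be sorted by (eps, dim, lexicographic
    vertex tuple) and face-closed.  Columns are stored as Python ints
    (bit i = row of the i-th simplex); the pivot is the highest set bit.
    Destroyer columns pair with the creator owning their pivot row.
    """
    index = {verts: i for i, (_, _, verts) in enumerate(simplices)}
    pivot_owner: dict[int, int] = {}
    columns: dict[int, int] = {}
    finite_pairs: list[tuple[int, float, float]] = []
    creators: list[int] = []
    for i, (eps, dim, verts) in enumerate(simplices):
        col = 0
        if dim > 0:
            for face in itertools.combinations(verts, dim):
                col |= 1 << index[face]
        while col:
            p = col.bit_length() - 1
            owner = pivot_owner.get(p)
            if owner is None:
                break
            col ^= columns[owner]
        if col:
            p = col.bit_length() - 1
            pivot_owner[p] = i
            columns[i] = col
            birth_eps, birth_dim, _ = simplices[p]
            finite_pairs.append((birth_dim, birth_eps, eps))
        else:
            creators.append(i)

    paired = set(pivot_owner)
    essential = [simplices[i] for i in creators
                 if i not in paired and simplices[i][1] <= max_dim]

    # dimension-0 conservation (before zero-length dropping)
    n0_finite = sum(1 for dim, _, _ in finite_pairs if dim == 0)
    n0_essential = sum(1 for _, dim, _ in essential if dim == 0)
    assert n0_finite + n0_essential == n_points, "dim-0 pair count broken"

    pairs = [PersistencePair(dim, float(b), float(d))
             for dim, b, d in finite_pairs if d > b]
    pairs += [PersistencePair(dim, float(eps), math.inf)
              for eps, dim, _ in essential]
    return PersistenceDiagram(tuple(pairs), max_dim, eps_max)


def _flag_filtration(edge_eps: np.ndarray, max_dim: int
                     ) -> list[tuple[float, int, tuple[int, ...]]]:
    """All flag (clique) simplices up to dim max_dim+1 with eps = max edge."""
    n = edge_eps.shape[0]
    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for k in range(max_dim + 2):
        for verts in itertools.combinations(range(n), k + 1):
            if k == 0:
                eps = 0.0
            else:
                eps = max(edge_eps[a, b] for a, b in itertools.combinations(verts, 2))
            simplices.append((eps, k, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    return simplices


def rips_persistence(d: DissimilarityMatrix | np.ndarray, max_dim: int = 2,
                     simplex_ceiling: int = DEFAULT_SIMPLEX_CEILING
                     ) -> PersistenceDiagram:
    """Full Vietoris-Rips persistence up to homology dimension ``max_dim``.

    Enumerates every simplex of dimension <= max_dim + 1 (a k-simplex
    enters the filtration at the maximum pairwise dissimilarity of its
    vertices), orders them by (eps, dim, lexicographic vertices) and
    runs the standard Z/2 lowest-one column reduction.

    Raises
    ------
    CapacityError
        If the enumeration would exceed ``simplex_ceiling`` simplices;
        use :func:`lazy_witness_persistence` for large clouds.
    """
    m = _as_matrix(d)
    n = m.shape[0]
    if not 0 <= max_dim <= 3:
        raise ValidationError("max_dim must be between 0 and 3")
    count = _simplex_count(n, max_dim + 1)
    if count > simplex_ceiling:
        raise CapacityError(
            f"Vietoris-Rips enumeration needs {count} simplices "
            f"(> ceiling {simplex_ceiling}); use lazy_witness_persistence"
        )
    return _reduce_filtration(_flag_filtration(m, max_dim), max_dim, n,
                              float(m.max(initial=0.0)))


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[max(ri, rj)] = min(ri, rj)
        return True


def zero_dim_persistence(d: DissimilarityMatrix | np.ndarray) -> PersistenceDiagram:
    """Exact dimension-0 persistence via Kruskal's algorithm.

    Every union of two components at edge weight ``w`` emits the pair
    (0, w); each surviving root is one essential component.  The finite
    death multiset equals the MST edge-weight multiset, so the summed
    death times SDT0 equal the total MST weight.
    """
    m = _as_matrix(d)
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, m[iu, ju]))  # weight, then (i, j) for determinism
    uf = _UnionFind(n)
    deaths: list[float] = []
    remaining = n - 1
    for k in order:
        if uf.union(int(iu[k]), int(ju[k])):
            deaths.append(float(m[iu[k], ju[k]]))
            remaining -= 1
            if remaining == 0:
                break
    n_essential = n - len(deaths)
    assert len(deaths) + n_essential == n  # dim-0 conservation
    pairs = [PersistencePair(0, 0.0, w) for w in deaths if w > 0.0]
    pairs += [PersistencePair(0, 0.0, math.inf)] * n_essential
    return PersistenceDiagram(tuple(pairs), 0, float(m.max(initial=0.0)))


@dataclass
class LandmarkSet:
    """Ordered landmark subset of a dissimilarity matrix's points."""

    indices: tuple[int, ...]
    method: str = "maxmin"
    seed: int = 0
    nu: int = 1

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValidationError("landmark indices must be distinct")
        if len(self.indices) < 2:
            raise ValidationError("need at least 2 landmarks")
        if self.nu < 0:
            raise ValidationError("nu must be >= 0")


def select_landmarks(d: DissimilarityMatrix | np.ndarray, k: int,
                     method: str = "maxmin", seed: int = 0,
                     nu: int = 1) -> LandmarkSet:
    """Choose ``k`` landmark points by maxmin or uniform random sampling.

    Maxmin starts deterministically from the point with the smallest
    row-sum (lowest index on ties) and then repeatedly adds the point
    maximising its minimum dissimilarity to the chosen landmarks (again
    lowest index on ties), giving a well-spread, fully reproducible set.
    """
    m = _as_matrix(d)
    n = m.shape[0]
    if not 2 <= k <= n:
        raise ValidationError(f"k must be in [2, {n}], got {k}")
    if method == "maxmin":
        start = int(np.argmin(m.sum(axis=1)))  # argmin takes the lowest index on ties
        chosen = [start]
        min_dist = m[start].copy()
        while len(chosen) < k:
            nxt = int(np.argmax(min_dist))
            chosen.append(nxt)
            min_dist = np.minimum(min_dist, m[nxt])
        return LandmarkSet(tuple(chosen), "maxmin", seed, nu)
    if method == "random":
        rng = np.random.default_rng(seed)
        chosen = rng.choice(n, size=k, replace=False)
        return LandmarkSet(tuple(int(i) for i in chosen), "random", seed, nu)
    raise ValidationError(f"unknown landmark method {method!r}")


def lazy_witness_persistence(d: DissimilarityMatrix | np.ndarray,
                             landmarks: LandmarkSet, max_dim: int = 3,
                             simplex_ceiling: int = DEFAULT_SIMPLEX_CEILING
                             ) -> PersistenceDiagram:
    """Lazy-witness persistence over a landmark subset.

    The vertex set is the landmarks.  For each non-landmark witness
    ``w``, let ``m(w)`` be the dissimilarity from ``w`` to its nu-th
    nearest landmark (nu = 0 means no relaxation).  Witness ``w`` puts
    edge {a, b} into the filtration at
    ``max(d(a, w), d(b, w)) - m(w)`` (clipped at 0); in addition every
    landmark pair witnesses its own edge at ``d(a, b)``, so with
    landmarks = all points the construction degenerates exactly to the
    Vietoris-Rips filtration for every nu.  Higher simplices enter when
    all their edges are present (lazy/flag rule); reduction and
    truncation are identical to :func:`rips_persistence`.
    """
    m = _as_matrix(d)
    n = m.shape[0]
    if not 0 <= max_dim <= 3:
        raise ValidationError("max_dim must be between 0 and 3")
    L = list(landmarks.indices)
    if any(not 0 <= i < n for i in L):
        raise ValidationError("landmark index out of range")
    nl = len(L)
    count = _simplex_count(nl, max_dim + 1)
    if count > simplex_ceiling:
        raise CapacityError(
            f"lazy-witness enumeration needs {count} simplices "
            f"(> ceiling {simplex_ceiling}); reduce the landmark count"
        )
    witnesses = [w for w in range(n) if w not in set(L)]
    # edge entry times among landmarks (indices relative to L)
    edge_eps = m[np.ix_(L, L)].copy()
    if witnesses and landmarks.nu > 0:
        d_wl = m[np.ix_(witnesses, L)]  # witnesses x landmarks
        nu = min(landmarks.nu, nl)
        m_w = np.sort(d_wl, axis=1)[:, nu - 1]
    elif witnesses:
        d_wl = m[np.ix_(witnesses, L)]
        m_w = np.zeros(len(witnesses))
    if witnesses:
        for a in range(nl):
            for b in range(a + 1, nl):
                t_wit = np.max(d_wl[:, [a, b]], axis=1) - m_w
                t = min(edge_eps[a, b], float(np.clip(t_wit, 0.0, None).min()))
                edge_eps[a, b] = edge_eps[b, a] = t
    np.fill_diagonal(edge_eps, 0.0)
    return _reduce_filtration(_flag_filtration(edge_eps, max_dim), max_dim, nl,
                              float(m.max(initial=0.0)))


class RipsPersistence(BaseEstimator, TransformerMixin):
    """Transformer computing Vietoris-Rips diagrams.

    ``transform`` maps a list of dissimilarity matrices (square ndarrays
    or :class:`~topohet.distances.DissimilarityMatrix`) to a list of
    :class:`PersistenceDiagram`; a single matrix yields a single diagram.
    """

    def __init__(self, max_dim: int = 2,
                 simplex_ceiling: int = DEFAULT_SIMPLEX_CEILING):
        self.max_dim = max_dim
        self.simplex_ceiling = simplex_ceiling

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        if isinstance(X, (list, tuple)):
            return [rips_persistence(x, self.max_dim, self.simplex_ceiling)
                    for x in X]
        return rips_persistence(X, self.max_dim, self.simplex_ceiling)


class LazyWitnessPersistence(BaseEstimator, TransformerMixin):
    """Transformer computing lazy-witness diagrams over auto-selected landmarks."""

    def __init__(self, n_landmarks: int = 20, method: str = "maxmin",
                 nu: int = 1, max_dim: int = 3, random_state: int = 0):
        self.n_landmarks = n_landmarks
        self.method = method
        self.nu = nu
        self.max_dim = max_dim
        self.random_state = random_state

    def fit(self, X, y=None):
        return self

    def _one(self, x) -> PersistenceDiagram:
        m = _as_matrix(x)
        k = min(self.n_landmarks, m.shape[0])
        lm = select_landmarks(m, k, self.method, self.random_state, self.nu)
        return lazy_witness_persistence(m, lm, self.max_dim)

    def transform(self, X):
        if isinstance(X, (list, tuple)):
            return [self._one(x) for x in X]
        return self._one(X)
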