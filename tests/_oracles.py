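"""Independent brute-force oracles used only by the test suite.

These deliberately share no code path with the package:

* ``brute_force_diagram`` computes a Vietoris-Rips persistence diagram
  from persistent Betti numbers obtained by plain GF(2) Gaussian
  elimination on boundary matrices, using the inclusion-exclusion
  multiplicity formula — a completely different algorithm from the
  package's lowest-one column reduction.
* ``exhaustive_split_fdr`` enumerates every equal split of a tiny
  design instead of sampling permutations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def gf2_rank(rows: list[int]) -> int:
    """Rank over GF(2) of a matrix given as integer bit-rows."""
    basis: dict[int, int] = {}
    rank = 0
    for row in rows:
        cur = row
        while cur:
            lead = cur.bit_length() - 1
            if lead in basis:
                cur ^= basis[lead]
            else:
                basis[lead] = cur
                rank += 1
                break
    return rank


def brute_force_diagram(d: np.ndarray, max_dim: int):
    """Rips persistence pairs [(dim, birth, death-or-inf), ...] by rank counting.

    For filtration steps i <= j over the critical epsilon values, the
    persistent Betti number is

        beta_k(i, j) = dim Z_k(K_i) - dim(B_k(K_j) ∩ C_k(K_i))

    with dim(B_k(K_j) ∩ C_k(K_i)) = rank D_j - rank(D_j with the rows
    of k-simplices in K_i deleted), D_j the partial (k+1)-boundary.
    Finite multiplicities follow by inclusion-exclusion over adjacent
    steps; essential classes from beta at the final complex.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]

    # simplices per dimension with VR filtration values
    simp: dict[int, list[tuple[tuple[int, ...], float]]] = {}
    for k in range(max_dim + 2):
        simp[k] = []
        for verts in itertools.combinations(range(n), k + 1):
            eps = 0.0 if k == 0 else max(
                d[a, b] for a, b in itertools.combinations(verts, 2))
            simp[k].append((verts, eps))

    crit = sorted({eps for sims in simp.values() for _, eps in sims})
    ncrit = len(crit)
    index_of = {k: {verts: r for r, (verts, _) in enumerate(simp[k])}
                for k in simp}

    def boundary_columns(k: int) -> list[tuple[int, float]]:
        """(column bitmask over (k-1)-simplex rows, eps) for each k-simplex."""
        cols = []
        for verts, eps in simp[k]:
            mask = 0
            for face in itertools.combinations(verts, k):
                mask |= 1 << index_of[k - 1][face]
            cols.append((mask, eps))
        return cols

    pairs = []
    for k in range(max_dim + 1):
        n_k = [sum(1 for _, eps in simp[k] if eps <= c) for c in crit]
        if k == 0:
            rank_dk = [0] * ncrit
        else:
            cols_k = boundary_columns(k)
            rank_dk = [gf2_rank([m for m, eps in cols_k if eps <= c])
                       for c in crit]
        z_dim = [n_k[i] - rank_dk[i] for i in range(ncrit)]

        cols_k1 = boundary_columns(k + 1)
        in_ki = [0] * ncrit  # bitmask of k-simplex rows present in K_i
        for r, (_, eps) in enumerate(simp[k]):
            for i, c in enumerate(crit):
                if eps <= c:
                    in_ki[i] |= 1 << r

        rank_dj = [gf2_rank([m for m, eps in cols_k1 if eps <= c])
                   for c in crit]

        def beta(i: int, j: int) -> int:
            if i < 0:
                return 0
            outside = ~in_ki[i]
            restricted = [m & outside for m, eps in cols_k1 if eps <= crit[j]]
            b_in_ci = rank_dj[j] - gf2_rank(restricted)
            return z_dim[i] - b_in_ci

        for a in range(ncrit):
            for b in range(a + 1, ncrit):
                mu = (beta(a, b - 1) - beta(a, b)) - (beta(a - 1, b - 1) - beta(a - 1, b))
                pairs.extend([(k, crit[a], crit[b])] * mu)
            mu_inf = beta(a, ncrit - 1) - beta(a - 1, ncrit - 1)
            pairs.extend([(k, crit[a], math.inf)] * mu_inf)
    return sorted(pairs)


def diagram_as_tuples(diagram) -> list[tuple[int, float, float]]:
    """Canonical multiset form of a package PersistenceDiagram."""
    return sorted((p.dim, float(p.birth), float(p.death)) for p in diagram.pairs)


def exhaustive_split_fdr(values: np.ndarray, labels_n: int,
                         stat_fn, sided: str = "two") -> float:
    """FDR by enumerating ALL equal splits of ``2 * labels_n`` samples.

    ``stat_fn(idx_case, idx_control) -> D``; the observed split is the
    first ``labels_n`` indices as controls, the rest as cases (matching
    the package's case = second group convention).
    """
    total = 2 * labels_n
    observed = stat_fn(tuple(range(labels_n, total)), tuple(range(labels_n)))
    ds = []
    for case in itertools.combinations(range(total), labels_n):
        control = tuple(i for i in range(total) if i not in case)
        ds.append(stat_fn(case, control))
    ds = np.asarray(ds)
    if sided == "two":
        return float(np.mean(np.abs(ds) >= abs(observed)))
    return float(np.mean(ds >= observed))
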