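import math

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

import topohet as th
from topohet.errors import CapacityError, ValidationError
from topohet.persistence import (
    LandmarkSet,
    PersistenceDiagram,
    PersistencePair,
    lazy_witness_persistence,
    rips_persistence,
    select_landmarks,
    zero_dim_persistence,
)

from _oracles import brute_force_diagram, diagram_as_tuples
from conftest import random_point_cloud_matrix, random_symmetric_matrix


def _matrix(entries, n):
    d = np.zeros((n, n))
    for (i, j), v in entries.items():
        d[i, j] = d[j, i] = v
    return d


SQUARE = _matrix({(0, 1): 1, (1, 2): 1, (2, 3): 1, (0, 3): 1,
                  (0, 2): 1.5, (1, 3): 1.5}, 4)


class TestRips:
    def test_two_points_merge_at_their_distance(self):
        diagram = rips_persistence(_matrix({(0, 1): 5.0}, 2), max_dim=1)
        assert diagram_as_tuples(diagram) == [(0, 0.0, 5.0), (0, 0.0, math.inf)]

    def test_single_point_is_one_essential_component(self):
        diagram = rips_persistence(np.zeros((1, 1)), max_dim=1)
        assert diagram_as_tuples(diagram) == [(0, 0.0, math.inf)]

    def test_square_has_one_loop(self):
        diagram = rips_persistence(SQUARE, max_dim=1)
        assert diagram_as_tuples(diagram) == [
            (0, 0.0, 1.0), (0, 0.0, 1.0), (0, 0.0, 1.0), (0, 0.0, math.inf),
            (1, 1.0, 1.5),
        ]

    @pytest.mark.parametrize("metric", [True, False])
    def test_matches_brute_force_oracle(self, metric):
        """Full reduction agrees with the independent GF(2) rank oracle."""
        rng = np.random.default_rng(17 if metric else 18)
        for _ in range(40):
            n = int(rng.integers(4, 8))
            d = (random_point_cloud_matrix(rng, n) if metric
                 else random_symmetric_matrix(rng, n))
            assert diagram_as_tuples(rips_persistence(d, max_dim=2)) \
                == brute_force_diagram(d, max_dim=2)

    def test_capacity_ceiling_enforced(self):
        with pytest.raises(CapacityError, match="lazy_witness"):
            rips_persistence(np.zeros((8, 8)), max_dim=2, simplex_ceiling=10)

    def test_nonfinite_matrix_rejected(self):
        d = _matrix({(0, 1): np.inf}, 2)
        with pytest.raises(ValidationError):
            rips_persistence(d, max_dim=1)

    def test_stability_under_bounded_perturbation(self):
        """Perturbing all distances by <= delta moves every death by <= delta."""
        rng = np.random.default_rng(5)
        d = random_point_cloud_matrix(rng, 8)
        delta = 0.01
        noise = rng.uniform(-delta, delta, size=d.shape)
        noise = np.triu(noise, 1)
        d2 = np.clip(d + noise + noise.T, 0, None)
        np.fill_diagonal(d2, 0.0)
        deaths1 = sorted(p.death for p in zero_dim_persistence(d).finite(0))
        deaths2 = sorted(p.death for p in zero_dim_persistence(d2).finite(0))
        assert np.allclose(deaths1, deaths2, atol=2 * delta)


class TestZeroDim:
    def test_line_points_die_at_gap_lengths(self):
        # 1-D points at 0, 1, 3: Kruskal unions at weights 1 then 2
        coords = np.array([[0.0], [1.0], [3.0]])
        d = squareform(pdist(coords))
        diagram = zero_dim_persistence(d)
        assert sorted(p.death for p in diagram.finite(0)) == [1.0, 2.0]
        assert len(diagram.essential(0)) == 1

    def test_identical_points_collapse_to_one_essential(self):
        diagram = zero_dim_persistence(np.zeros((5, 5)))
        assert diagram.finite(0) == ()  # zero-length pairs dropped
        assert len(diagram.essential(0)) == 1
        assert th.summarize(diagram).sdt0 == 0.0

    def test_finite_deaths_are_the_mst_edge_weights(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(3, 40))
            d = random_symmetric_matrix(rng, n)
            deaths = sorted(p.death for p in zero_dim_persistence(d).finite(0))
            mst = minimum_spanning_tree(d).tocoo().data
            assert np.allclose(deaths, sorted(mst), atol=1e-12)

    def test_agrees_with_full_reduction_dimension_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            d = random_symmetric_matrix(rng, int(rng.integers(3, 10)))
            fast = diagram_as_tuples(zero_dim_persistence(d))
            full = [t for t in diagram_as_tuples(rips_persistence(d, max_dim=0))
                    if t[0] == 0]
            assert fast == full


class TestLandmarks:
    def test_k_equals_n_selects_all_points(self):
        d = random_point_cloud_matrix(np.random.default_rng(0), 6)
        for method in ("maxmin", "random"):
            lm = select_landmarks(d, 6, method=method, seed=1)
            assert sorted(lm.indices) == list(range(6))

    def test_maxmin_on_a_line_has_nonincreasing_coverage_radius(self):
        d = squareform(pdist(np.arange(10.0)[:, None]))
        radii = []
        for k in range(2, 11):
            lm = select_landmarks(d, k, method="maxmin")
            rest = [i for i in range(10)]
            cover = max(min(d[i, j] for j in lm.indices) for i in rest)
            radii.append(cover)
        assert all(a >= b for a, b in zip(radii, radii[1:]))

    def test_maxmin_start_is_lowest_index_minimum_row_sum(self):
        d = squareform(pdist(np.arange(10.0)[:, None]))
        # row sums tie at coordinates 4 and 5; lowest index wins
        assert select_landmarks(d, 2, method="maxmin").indices[0] == 4

    def test_random_selection_deterministic_given_seed(self):
        d = random_point_cloud_matrix(np.random.default_rng(0), 12)
        a = select_landmarks(d, 5, method="random", seed=9)
        b = select_landmarks(d, 5, method="random", seed=9)
        assert a.indices == b.indices

    def test_k_out_of_range_rejected(self):
        d = random_point_cloud_matrix(np.random.default_rng(0), 5)
        for k in (1, 6):
            with pytest.raises(ValidationError):
                select_landmarks(d, k)


class TestLazyWitness:
    def test_all_landmarks_degenerates_to_rips(self):
        """With every point a landmark there are no witnesses left to
        relax anything, so the filtration is exactly Vietoris-Rips."""
        rng = np.random.default_rng(21)
        for trial in range(20):
            n = int(rng.integers(3, 8))
            d = (random_point_cloud_matrix(rng, n) if trial % 2
                 else random_symmetric_matrix(rng, n))
            lm = select_landmarks(d, n, method="maxmin", nu=1)
            assert diagram_as_tuples(lazy_witness_persistence(d, lm, max_dim=2)) \
                == diagram_as_tuples(rips_persistence(d, max_dim=2))

    def test_triangle_component_deaths(self):
        d = _matrix({(0, 1): 3.0, (0, 2): 4.0, (1, 2): 5.0}, 3)
        lm = LandmarkSet((0, 1, 2), "maxmin", 0, 1)
        diagram = lazy_witness_persistence(d, lm, max_dim=1)
        assert sorted(p.death for p in diagram.finite(0)) == [3.0, 4.0]

    def test_dim0_count_conservation(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d = random_point_cloud_matrix(rng, 15)
            lm = select_landmarks(d, 6, method="maxmin")
            diagram = lazy_witness_persistence(d, lm, max_dim=1)
            assert len(diagram.finite(0)) == 6 - len(diagram.essential(0))

    def test_witnesses_sparsify_but_keep_dim0_of_landmark_rips(self):
        """Witness edges only ever appear EARLIER than the landmark
        Rips edges, so dimension-0 deaths cannot increase."""
        rng = np.random.default_rng(6)
        d = random_point_cloud_matrix(rng, 20)
        lm = select_landmarks(d, 8, method="maxmin")
        sub = d[np.ix_(lm.indices, lm.indices)]
        lw_deaths = sorted(p.death for p in
                           lazy_witness_persistence(d, lm, max_dim=0).finite(0))
        vr_deaths = sorted(p.death for p in zero_dim_persistence(sub).finite(0))
        assert all(a <= b + 1e-12 for a, b in zip(lw_deaths, vr_deaths))


class TestDiagramIO:
    def test_tsv_round_trip_preserves_pairs(self, tmp_path):
        diagram = rips_persistence(SQUARE, max_dim=1)
        path = diagram.to_tsv(tmp_path / "d.tsv")
        back = PersistenceDiagram.from_tsv(path)
        assert diagram_as_tuples(back) == diagram_as_tuples(diagram)

    def test_canonical_sort_order(self):
        diagram = PersistenceDiagram(
            (PersistencePair(1, 0.5, 1.0), PersistencePair(0, 0.0, 2.0),
             PersistencePair(0, 0.0, 1.0)), max_dim=1, eps_max=2.0)
        assert [p.dim for p in diagram.pairs] == [0, 0, 1]
        assert diagram.pairs[0].death == 1.0
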