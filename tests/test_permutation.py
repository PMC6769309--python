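import numpy as np
import pytest

import topohet as th
from topohet.errors import GroupContractError, ValidationError
from topohet.permutation import (
    GroupStatistic,
    TopologyPermutationTest,
    _fdr,
    group_statistic_difference,
)

from conftest import make_expr


def _split(ds):
    control, case = (ds.expression.subset_samples(ds.metadata.samples_in(g))
                     for g in ds.metadata.groups)
    return case, control


class TestGroupDifference:
    def test_identical_groups_give_exactly_zero(self, null_dataset):
        expr = null_dataset.expression
        half = expr.subset_samples(expr.sample_ids[:15])
        stat = GroupStatistic("sdt0", "sample")
        assert group_statistic_difference(half, half, stat) == 0.0

    def test_antisymmetric_under_group_swap(self, heterogeneous_dataset):
        case, control = _split(heterogeneous_dataset)
        for kind in ("sdt0", "euler"):
            stat = GroupStatistic(kind, "sample")
            d1 = group_statistic_difference(case, control, stat)
            d2 = group_statistic_difference(control, case, stat)
            assert d1 == pytest.approx(-d2, abs=1e-12)

    def test_heterogeneous_case_group_gives_positive_d(self):
        signs = []
        for seed in range(10):
            ds = th.generate(th.SyntheticConfig(n_genes=60, n_per_group=15,
                                                heterogeneity=3.0, seed=seed))
            case, control = _split(ds)
            signs.append(group_statistic_difference(
                case, control, GroupStatistic("sdt0", "sample")) > 0)
        assert all(signs)

    def test_mismatched_gene_universe_rejected(self, null_dataset):
        case, control = _split(null_dataset)
        with pytest.raises(GroupContractError):
            group_statistic_difference(
                case.subset_genes(case.gene_ids[:30]), control,
                GroupStatistic("sdt0", "sample"))

    def test_unequal_sample_counts_rejected(self, null_dataset):
        case, control = _split(null_dataset)
        with pytest.raises(GroupContractError):
            group_statistic_difference(
                case.subset_samples(case.sample_ids[:10]), control,
                GroupStatistic("sdt0", "sample"))

    def test_gene_level_statistic_is_deterministic(self, null_dataset):
        case, control = _split(null_dataset)
        stat = GroupStatistic("sdt0", "gene", landmark_size=10)
        d1 = group_statistic_difference(case, control, stat, (3, 4))
        d2 = group_statistic_difference(case, control, stat, (3, 4))
        assert d1 == d2


class TestLabelPermutation:
    def test_same_seed_reproduces_null_values(self, null_dataset):
        stat = GroupStatistic("sdt0", "sample")
        kw = dict(n_perm=20, seed=123)
        r1 = th.label_permutation_test(null_dataset.expression,
                                       null_dataset.metadata, stat, **kw)
        r2 = th.label_permutation_test(null_dataset.expression,
                                       null_dataset.metadata, stat, **kw)
        assert np.array_equal(r1.null_values, r2.null_values)
        assert r1.observed == r2.observed

    def test_zero_observed_with_symmetric_null_gives_fdr_one(self):
        # duplicated matrix: the case block equals the control block
        rng = np.random.default_rng(0)
        block = rng.normal(size=(20, 6))
        expr = make_expr(np.column_stack([block, block]))
        meta = th.SampleMetadata({s: ("a" if i < 6 else "b")
                                  for i, s in enumerate(expr.sample_ids)})
        r = th.label_permutation_test(expr, meta, GroupStatistic("sdt0", "sample"),
                                      n_perm=25, seed=1)
        assert r.observed == 0.0
        assert r.fdr == 1.0

    def test_fdr_invariant_under_case_label_choice(self, heterogeneous_dataset):
        stat = GroupStatistic("sdt0", "sample")
        rs = [th.label_permutation_test(
            heterogeneous_dataset.expression, heterogeneous_dataset.metadata,
            stat, n_perm=50, seed=7, case_label=lab)
            for lab in heterogeneous_dataset.metadata.groups]
        assert rs[0].observed == pytest.approx(-rs[1].observed, abs=1e-12)
        assert rs[0].fdr == rs[1].fdr  # two-sided rule only sees |D|

    def test_strong_heterogeneity_detected(self, heterogeneous_dataset):
        r = th.label_permutation_test(
            heterogeneous_dataset.expression, heterogeneous_dataset.metadata,
            GroupStatistic("sdt0", "sample"), n_perm=99, seed=0)
        assert r.observed > 0
        assert r.fdr <= 0.05

    def test_gene_level_permutation_runs_and_is_deterministic(self, null_dataset):
        stat = GroupStatistic("sdt0", "gene", landmark_size=8)
        r1 = th.label_permutation_test(null_dataset.expression,
                                       null_dataset.metadata, stat,
                                       n_perm=5, seed=2)
        r2 = th.label_permutation_test(null_dataset.expression,
                                       null_dataset.metadata, stat,
                                       n_perm=5, seed=2)
        assert np.array_equal(r1.null_values, r2.null_values)

    def test_n_perm_below_one_rejected(self, null_dataset):
        with pytest.raises(ValidationError):
            th.label_permutation_test(null_dataset.expression,
                                      null_dataset.metadata,
                                      GroupStatistic(), n_perm=0)

    def test_sided_rules(self):
        null = np.array([-3.0, -1.0, 0.5, 2.0])
        assert _fdr(1.0, null, "two") == 0.75
        assert _fdr(1.0, null, "greater") == 0.25
        with pytest.raises(ValidationError):
            _fdr(1.0, null, "less")

    def test_estimator_interface_matches_function(self, heterogeneous_dataset):
        est = TopologyPermutationTest(n_perm=30, random_state=4)
        est.fit(heterogeneous_dataset.expression, heterogeneous_dataset.metadata)
        ref = th.label_permutation_test(
            heterogeneous_dataset.expression, heterogeneous_dataset.metadata,
            GroupStatistic("sdt0", "sample"), n_perm=30, seed=4)
        assert est.observed_ == ref.observed
        assert np.array_equal(est.null_values_, ref.null_values)
        assert est.get_params()["n_perm"] == 30

    def test_estimator_accepts_plain_arrays(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 30))  # samples x genes
        y = ["a"] * 5 + ["b"] * 5
        est = TopologyPermutationTest(n_perm=10).fit(X, y)
        assert 0.0 <= est.fdr_ <= 1.0


class TestGeneSetScan:
    def test_filter_keeps_sets_with_at_least_half_expressed(self):
        expr = make_expr(np.random.default_rng(0).normal(size=(5, 4)),
                         gene_ids=tuple("ABCDE"))
        sets = th.GeneSetCollection({
            "half": th.GeneSet("half", "", ("A", "B", "C", "D", "E",
                                            "X1", "X2", "X3", "X4", "X5")),
            "less": th.GeneSet("less", "", ("A", "B", "X1", "X2", "X3")),
        })
        kept = th.filter_genesets(sets, expr)
        assert list(s.name for s in kept) == ["half"]
        assert kept["half"].genes == ("A", "B", "C", "D", "E")

    def test_filter_empty_collection(self):
        expr = make_expr(np.ones((2, 2)) + np.arange(2))
        assert len(th.filter_genesets(th.GeneSetCollection({}), expr)) == 0

    def test_affected_set_flagged_decoys_not(self, restricted_dataset, tmp_path):
        paths = th.write_fixture(restricted_dataset, tmp_path, n_decoys=2)
        sets = th.filter_genesets(th.read_gmt(paths["gmt"]),
                                  restricted_dataset.expression)
        scan = th.geneset_topology_scan(
            restricted_dataset.expression, restricted_dataset.metadata, sets,
            GroupStatistic("sdt0", "sample"), n_random=49, seed=3)
        assert scan.per_set["affected"].fdr <= 0.05
        assert scan.per_set["affected"].observed_d > 0

    def test_small_sets_skipped_with_warning(self, null_dataset, caplog):
        sets = th.GeneSetCollection({
            "tiny": th.GeneSet("tiny", "", null_dataset.expression.gene_ids[:2]),
            "ok": th.GeneSet("ok", "", null_dataset.expression.gene_ids[:5]),
        })
        with caplog.at_level("WARNING"):
            scan = th.geneset_topology_scan(
                null_dataset.expression, null_dataset.metadata, sets,
                GroupStatistic("sdt0", "sample"), n_random=5, seed=0)
        assert scan.skipped == ("tiny",)
        assert "tiny" in caplog.text
        assert set(scan.per_set) == {"ok"}

    def test_zero_random_sets_rejected(self, null_dataset):
        sets = th.GeneSetCollection(
            {"ok": th.GeneSet("ok", "", null_dataset.expression.gene_ids[:5])})
        with pytest.raises(ValidationError):
            th.geneset_topology_scan(null_dataset.expression,
                                     null_dataset.metadata, sets,
                                     GroupStatistic("sdt0", "sample"),
                                     n_random=0)

    def test_gene_level_statistic_refused(self, null_dataset):
        sets = th.GeneSetCollection(
            {"ok": th.GeneSet("ok", "", null_dataset.expression.gene_ids[:5])})
        with pytest.raises(ValidationError):
            th.geneset_topology_scan(null_dataset.expression,
                                     null_dataset.metadata, sets,
                                     GroupStatistic("sdt0", "gene"), n_random=5)

    def test_tsv_export(self, null_dataset, tmp_path):
        sets = th.GeneSetCollection(
            {"ok": th.GeneSet("ok", "", null_dataset.expression.gene_ids[:6])})
        scan = th.geneset_topology_scan(null_dataset.expression,
                                        null_dataset.metadata, sets,
                                        GroupStatistic("sdt0", "sample"),
                                        n_random=5, seed=0)
        path = scan.to_tsv(tmp_path / "scan.tsv")
        lines = path.read_text().splitlines()
        assert lines[0].startswith("set_name")
        assert lines[1].split("\t")[0] == "ok"
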