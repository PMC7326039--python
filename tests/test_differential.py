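import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circgrade.differential import (
    anova_per_feature,
    bh_adjust,
    cluster_matrix,
    group_purity,
    significant_sets,
)
from circgrade.errors import ValidationError


def _samples(groups):
    rows = []
    for grade, n in groups.items():
        for i in range(n):
            rows.append((f"{grade}_{i}", grade))
    return pd.DataFrame(rows, columns=["sample_id", "grade"])


def _matrix(rows, samples):
    return pd.DataFrame(rows, columns=samples["sample_id"],
                        index=[f"f{i}" for i in range(len(rows))])


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        samples = _samples({"G1": 3, "G3": 3})
        rel = _matrix([[1, 2, 3, 1, 2, 3]], samples)
        res = anova_per_feature(rel, samples)
        assert res["F"].iloc[0] == pytest.approx(0.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_tiny_jitter(self):
        samples = _samples({"G1": 4, "G3": 4})
        jitter = [1e-4, -1e-4, 2e-4, -2e-4]
        rel = _matrix([[0 + j for j in jitter] + [5 + j for j in jitter]], samples)
        res = anova_per_feature(rel, samples)
        assert res["p_value"].iloc[0] < 1e-6

    def test_textbook_three_group_arithmetic(self):
        """F must equal the between/within mean-square ratio computed by
        hand: groups [1,2,3], [2,3,4], [4,5,6] give SSB=14, SSW=6, F=7."""
        samples = _samples({"G1": 3, "G2": 3, "G3": 3})
        rel = _matrix([[1, 2, 3, 2, 3, 4, 4, 5, 6]], samples)
        res = anova_per_feature(rel, samples)
        assert res["F"].iloc[0] == pytest.approx(7.0)
        assert res["p_value"].iloc[0] == pytest.approx(
            float(stats.f.sf(7.0, 2, 6))
        )
        assert res["mean_G1"].iloc[0] == pytest.approx(2.0)
        assert res["mean_G3"].iloc[0] == pytest.approx(5.0)

    def test_constant_within_groups_but_separated_is_significant(self):
        samples = _samples({"G1": 3, "G3": 3})
        rel = _matrix([[0, 0, 0, 5, 5, 5]], samples)
        res = anova_per_feature(rel, samples)
        assert res["p_value"].iloc[0] == 0.0

    def test_small_group_rejected_by_name(self):
        samples = _samples({"G1": 1, "G3": 3})
        rel = _matrix([[1, 2, 3, 4]], samples)
        with pytest.raises(ValidationError, match="G1"):
            anova_per_feature(rel, samples)

    def test_matches_scipy_on_random_matrix(self, rng):
        samples = _samples({"G1": 5, "G2": 4, "G3": 6})
        rel = _matrix(rng.normal(size=(50, 15)), samples)
        res = anova_per_feature(rel, samples)
        g = samples.set_index("sample_id")["grade"]
        for fid in ["f0", "f17", "f49"]:
            blocks = [
                rel.loc[fid, g.index[g == lvl]].to_numpy()
                for lvl in ("G1", "G2", "G3")
            ]
            F, p = stats.f_oneway(*blocks)
            assert res.loc[fid, "F"] == pytest.approx(F)
            assert res.loc[fid, "p_value"] == pytest.approx(p)


class TestBH:
    def test_hand_stepup_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(size=60)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSignificantSets:
    def _results(self, pvals):
        return pd.DataFrame(
            {"adjusted_p": pvals}, index=[f"c{i}" for i in range(len(pvals))]
        )

    def test_no_significant_circles_all_empty(self):
        res = self._results([0.9, 0.5])
        sets = significant_sets(res, {"c0": "A", "c1": "B"}, genes_de=["B"],
                                all_circle_hosts=["A", "B"])
        assert sets["de_circles"] == set()
        assert sets["de_circle_hosts"] == set()
        assert sets["circles_decoupled_from_host"] == set()
        assert sets["de_genes_with_circles"] == {"B"}

    def test_toy_set_algebra(self):
        res = self._results([0.01] * 5)
        hosts = {"c0": "A", "c1": "A", "c2": "B", "c3": "C", "c4": "D"}
        sets = significant_sets(res, hosts, genes_de=["B", "C"])
        assert sets["de_circle_hosts"] == {"A", "B", "C", "D"}
        assert sets["circles_decoupled_from_host"] == {"c0", "c1", "c4"}
        assert sets["de_genes_with_circles"] == {"B", "C"}

    def test_all_hosts_gene_level_de_gives_no_decoupled(self):
        res = self._results([0.01, 0.02])
        hosts = {"c0": "A", "c1": "B"}
        sets = significant_sets(res, hosts, genes_de=["A", "B"])
        assert sets["circles_decoupled_from_host"] == set()


class TestCluster:
    def test_two_identical_row_blocks_recovered(self):
        block_a = np.tile([0.0, 0.0, 5.0, 5.0], (4, 1))
        block_b = np.tile([5.0, 5.0, 0.0, 0.0], (3, 1))
        m = pd.DataFrame(
            np.vstack([block_a, block_b]),
            index=[f"f{i}" for i in range(7)],
            columns=[f"s{i}" for i in range(4)],
        )
        result = cluster_matrix(m)
        clusters = result.feature_clusters
        assert set(clusters[:4]) == {1} and set(clusters[4:]) == {2}

    def test_sample_permutation_gives_same_partition_sets(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(10, 8)),
            index=[f"f{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(8)],
        )
        base = cluster_matrix(m)
        perm = rng.permutation(8)
        shuffled = cluster_matrix(m.iloc[:, perm])
        def groups_as_sets(res):
            return {
                frozenset(res.sample_groups.index[res.sample_groups == g])
                for g in ("A", "B")
            }
        assert groups_as_sets(base) == groups_as_sets(shuffled)

    def test_constant_matrix_rejected(self):
        m = pd.DataFrame(np.ones((3, 3)))
        with pytest.raises(ValidationError):
            cluster_matrix(m)

    def test_spiked_signature_separates_high_grade(self, small_cohort,
                                                   sim_annotation):
        """Clustering the truly grade-shifted junctions' relative expression
        splits off a sample group dominated by G3."""
        from circgrade import pipeline

        res = pipeline.run_pipeline(
            small_cohort.samples, small_cohort.linear_table, sim_annotation,
            circ_counts=small_cohort.circ_counts, min_reads=1,
        )
        spiked = small_cohort.truth.query("is_spiked")["feature_id"]
        result = cluster_matrix(res.rel_expr.loc[spiked])
        grades = small_cohort.samples.set_index("sample_id")["grade"]
        purity = group_purity(result.sample_groups, grades)
        # majority-label purity over both groups; G3 is 36/58 overall
        assert purity > 0.75
        g3_frac = {
            g: (grades[result.sample_groups.index[result.sample_groups == g]]
                == "G3").mean()
            for g in ("A", "B")
        }
        assert max(g3_frac.values()) > 0.9
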