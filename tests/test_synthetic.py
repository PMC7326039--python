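import numpy as np
import pandas as pd
import pytest

from circgrade import backsplice
from circgrade.errors import ConfigurationError
from circgrade.pipeline import junctions_from_counts
from circgrade.synthetic import (
    SamplePlan,
    SpikeConfig,
    generate_annotation,
    generate_cohort,
    generate_gene_counts,
    generate_reference_cohort,
    generate_site_table,
)


class TestAnnotation:
    def test_deterministic_given_seed(self):
        a = generate_annotation(seed=1, n_genes=10)
        b = generate_annotation(seed=1, n_genes=10)
        assert a.gene_ids == b.gene_ids
        for g in a.gene_ids:
            assert a.exons[g] == b.exons[g]
            assert a.cds_regions[g] == b.cds_regions[g]

    def test_single_exon_gene_tiles_utr_cds_utr(self):
        db = generate_annotation(seed=3, n_genes=1, exons_per_gene_range=(1, 1))
        [gene] = db.genes
        exon = db.exons[gene.gene_id][0]
        pieces = (
            db.utr5_regions[gene.gene_id]
            + db.cds_regions[gene.gene_id]
            + db.utr3_regions[gene.gene_id]
        )
        covered = sorted((iv.start, iv.end) for iv in pieces)
        assert covered[0][0] == exon.start and covered[-1][1] == exon.end
        assert sum(e - s for s, e in covered) == len(exon)

    def test_zero_genes_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_annotation(seed=1, n_genes=0)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ConfigurationError, match="packing"):
            generate_annotation(seed=1, n_genes=500, chrom_count=1,
                                chrom_length=100_000)

    def test_genes_non_overlapping_per_chromosome(self, sim_annotation):
        by_chrom = {}
        for g in sim_annotation.genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs = sorted(ivs, key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start


class TestCohort:
    def test_default_plan_is_58_samples_17_5_36(self, small_cohort):
        counts = small_cohort.samples["grade"].value_counts()
        assert len(small_cohort.samples) == 58
        assert counts["G1"] == 17 and counts["G2"] == 5 and counts["G3"] == 36
        stages = small_cohort.samples["stage_class"].value_counts()
        assert stages["MIBC"] == 6
        assert (
            small_cohort.samples.loc[
                small_cohort.samples.stage_class == "MIBC", "grade"
            ]
            == "G3"
        ).all()

    def test_deterministic_byte_identical_outputs(self, sim_annotation, tmp_path):
        for d in ("a", "b"):
            generate_cohort(
                sim_annotation, n_junctions=50, seed=5,
                spike=SpikeConfig(n_spiked=5, effect_size=1.0),
            ).write(tmp_path / d)
        for name in ("samples.tsv", "truth.tsv", "circ_counts.tsv",
                     "linear.tsv", "chimeric.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_null_spike_means_equal_across_grades(self, sim_annotation):
        cohort = generate_cohort(
            sim_annotation, n_junctions=30,
            spike=SpikeConfig(n_spiked=10, effect_size=0.0), seed=2,
        )
        truth = cohort.truth
        assert np.allclose(truth["true_mean_G1"], truth["true_mean_G3"])
        assert np.allclose(truth["true_mean_G1"], truth["true_mean_G2"])

    def test_spiked_count_matches_config(self, small_cohort):
        assert small_cohort.truth["is_spiked"].sum() == 40

    def test_overspiking_rejected(self, sim_annotation):
        with pytest.raises(ConfigurationError):
            generate_cohort(
                sim_annotation, n_junctions=5,
                spike=SpikeConfig(n_spiked=6, effect_size=1.0), seed=0,
            )

    def test_context_mix_within_two_points_at_1000(self, sim_annotation):
        cohort = generate_cohort(
            sim_annotation, n_junctions=1000, seed=9, with_chimeric=False
        )
        mix = cohort.truth["context"].value_counts(normalize=True)
        assert abs(mix.get("exonic", 0) - 0.94) <= 0.02
        assert abs(mix.get("intronic", 0) - 0.04) <= 0.02
        assert abs(mix.get("intergenic", 0) - 0.02) <= 0.02

    def test_spike_effect_converges_at_n200_per_grade(self, sim_annotation):
        """Empirical grade contrast of spiked junctions approaches the
        configured effect size once the per-grade sample count is large."""
        plan = SamplePlan(n_g1=200, n_g2=2, n_g3=200, n_mibc=0)
        cohort = generate_cohort(
            sim_annotation, sample_plan=plan, n_junctions=300,
            spike=SpikeConfig(n_spiked=100, effect_size=1.0, direction="up"),
            seed=31, with_chimeric=False,
        )
        from circgrade import quantify

        lib = cohort.samples.set_index("sample_id")["library_size"]
        junctions = junctions_from_counts(cohort.circ_counts)
        lin = quantify.resolve_linear_counts(
            junctions, cohort.linear_table, lib
        )
        rel = quantify.relative_expression(
            quantify.cpm(cohort.circ_counts), quantify.cpm(lin)
        )
        g3 = cohort.samples.sample_id[cohort.samples.grade == "G3"]
        g1 = cohort.samples.sample_id[cohort.samples.grade == "G1"]
        diff = rel[list(g3)].mean(axis=1) - rel[list(g1)].mean(axis=1)
        spiked = cohort.truth.set_index("feature_id")["is_spiked"]
        observed = diff[spiked.reindex(diff.index).to_numpy(dtype=bool)].mean()
        assert abs(observed - 1.0) < 0.1

    def test_chimeric_reads_reproduce_drawn_counts(self, small_cohort):
        """Summing qualifying chimeric records per junction and sample must
        give back exactly the counts the generator drew."""
        called = backsplice.call_backsplices(small_cohort.chimeric)
        called_counts = {j.key: j.counts for j in called}
        expected = junctions_from_counts(small_cohort.circ_counts)
        for j in expected:
            assert called_counts.get(j.key, {}) == j.counts
        assert len(expected) == small_cohort.circ_counts.counts.shape[0]


class TestSiteTable:
    def test_all_canonical_when_frac_long_zero(self, sim_annotation):
        sites = generate_site_table(sim_annotation, 500, 0.0, seed=1)
        assert set(sites["end"] - sites["start"]) <= {7, 8}

    def test_exact_long_site_count(self, sim_annotation):
        n_sites = 5000
        frac = 192 / 122607
        sites = generate_site_table(sim_annotation, n_sites, frac, seed=2)
        assert ((sites["end"] - sites["start"]) > 8).sum() == round(frac * n_sites)

    def test_deterministic(self, sim_annotation):
        a = generate_site_table(sim_annotation, 200, 0.1, seed=3)
        b = generate_site_table(sim_annotation, 200, 0.1, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_sites_inside_genes(self, sim_annotation):
        sites = generate_site_table(sim_annotation, 300, 0.0, seed=4)
        for row in sites.itertuples(index=False):
            genes = sim_annotation.genes_at(row.chrom, row.start)
            assert genes, "site start outside any gene"


class TestReferenceCohort:
    def _keys(self, n=200):
        return [("chr1", 1000 + 10 * i, 1500 + 10 * i) for i in range(n)]

    def test_full_match_zero_offset_equals_input(self):
        keys = self._keys(50)
        ref = generate_reference_cohort(keys, 1.0, 0, seed=1)
        assert set(map(tuple, ref.to_numpy())) == set(keys)

    def test_zero_match_after_unification(self):
        keys = self._keys(50)
        ref = generate_reference_cohort(keys, 0.0, 0, seed=1)
        assert set(map(tuple, ref.to_numpy())).isdisjoint(set(keys))

    def test_half_match_gives_exact_count(self):
        keys = self._keys(200)
        ref = generate_reference_cohort(keys, 0.5, 1, seed=2)
        # brute-force intersection after removing the +1 start offset
        unified = {(c, s - 1, e) for c, s, e in map(tuple, ref.to_numpy())}
        assert len(unified & set(keys)) == 100

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_reference_cohort([], 0.5, 0, seed=1)


def test_gene_counts_have_declared_de_genes(sim_annotation, small_samples):
    cm, de = generate_gene_counts(sim_annotation, small_samples, seed=5,
                                  de_fraction=0.2)
    assert len(de) == round(0.2 * len(sim_annotation.gene_ids))
    assert cm.counts.shape == (len(sim_annotation.gene_ids), 58)
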