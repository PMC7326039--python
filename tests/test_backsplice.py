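import numpy as np
import pytest

from circgrade.backsplice import (
    BackspliceJunction,
    ChimericRecord,
    call_backsplices,
    classify_context,
    context_fractions,
    filter_junctions,
    is_backsplice,
    positional_bias,
    summarize_candidates,
)
from circgrade.errors import ConfigurationError, ValidationError
from circgrade.intervals import GenomicInterval


def rec(sample, donor, acceptor, read_id="r1"):
    return ChimericRecord(sample, donor, acceptor, read_id)


class TestCalling:
    def test_plus_strand_head_to_tail_called(self):
        [j] = call_backsplices(
            [rec("s1", ("chr1", 500, "+"), ("chr1", 100, "+"))]
        )
        assert j.interval == GenomicInterval("chr1", 100, 500, "+")
        assert j.counts == {"s1": 1}

    def test_linear_orientation_skipped(self):
        assert call_backsplices(
            [rec("s1", ("chr1", 100, "+"), ("chr1", 500, "+"))]
        ) == []

    def test_trans_chromosomal_skipped(self):
        assert call_backsplices(
            [rec("s1", ("chr1", 500, "+"), ("chr2", 100, "+"))]
        ) == []

    def test_minus_strand_orientation_reversed(self):
        # on minus, transcription runs right to left: donor < acceptor
        [j] = call_backsplices(
            [rec("s1", ("chr1", 100, "-"), ("chr1", 500, "-"))]
        )
        assert j.interval == GenomicInterval("chr1", 100, 500, "-")
        assert call_backsplices(
            [rec("s1", ("chr1", 500, "-"), ("chr1", 100, "-"))]
        ) == []

    def test_max_span_excludes_long_junctions(self):
        records = [rec("s1", ("chr1", 2_000_000, "+"), ("chr1", 10, "+"))]
        assert call_backsplices(records) == []
        assert len(call_backsplices(records, max_span=3_000_000)) == 1

    def test_counts_merge_per_sample_and_duplicates_once(self):
        records = [
            rec("s1", ("chr1", 500, "+"), ("chr1", 100, "+"), "a"),
            rec("s1", ("chr1", 500, "+"), ("chr1", 100, "+"), "b"),
            rec("s1", ("chr1", 500, "+"), ("chr1", 100, "+"), "b"),  # PCR dup
            rec("s2", ("chr1", 500, "+"), ("chr1", 100, "+"), "a"),
        ]
        [j] = call_backsplices(records)
        assert j.counts == {"s1": 2, "s2": 1}

    def test_permutation_invariance(self, rng):
        records = []
        for i in range(300):
            chrom = f"chr{rng.integers(1, 4)}"
            a, b = sorted(rng.integers(0, 10_000, size=2))
            strand = "+" if rng.random() < 0.5 else "-"
            donor_pos, acceptor_pos = (b, a) if strand == "+" else (a, b)
            records.append(
                rec(
                    f"s{rng.integers(1, 4)}",
                    (chrom, int(donor_pos), strand),
                    (chrom, int(acceptor_pos), strand),
                    f"r{i}",
                )
            )
        base = call_backsplices(records)
        perm = call_backsplices([records[i] for i in rng.permutation(len(records))])
        assert [j.key for j in base] == [j.key for j in perm]
        assert [j.counts for j in base] == [j.counts for j in perm]

    def test_qualifying_plus_skipped_equals_input(self, rng):
        """No record is lost: every input is either a counted supporting
        read, a duplicate, or fails the head-to-tail predicate."""
        records = []
        for i in range(500):
            chrom = "chr1"
            d, a = rng.integers(0, 5_000, size=2)
            if d == a:
                continue
            records.append(
                rec("s1", (chrom, int(d), "+"), (chrom, int(a), "+"), f"r{i}")
            )
        junctions = call_backsplices(records)
        n_counted = sum(j.total_count() for j in junctions)
        n_qualifying = sum(is_backsplice(r) for r in records)
        assert n_counted == n_qualifying  # read ids unique here

    def test_output_sorted(self, small_cohort):
        junctions = call_backsplices(small_cohort.chimeric)
        keys = [j.key for j in junctions]
        assert keys == sorted(keys)


class TestFilter:
    def _junction(self, counts):
        return BackspliceJunction(GenomicInterval("chr1", 1, 2), counts=counts)

    @pytest.mark.parametrize(
        "counts,min_reads,min_samples,kept",
        [
            ({"s1": 4}, 4, 1, True),  # boundary
            ({"s1": 3, "s2": 3}, 4, 1, False),
            ({"s1": 2, "s2": 2}, 2, 2, True),
            ({"s1": 5, "s2": 1}, 4, 2, False),
            ({}, 4, 1, False),
        ],
    )
    def test_support_predicate(self, counts, min_reads, min_samples, kept):
        result = filter_junctions(
            [self._junction(counts)], min_reads=min_reads, min_samples=min_samples
        )
        assert (len(result) == 1) is kept

    def test_min_reads_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_junctions([], min_reads=0)

    def test_order_preserved(self):
        js = [
            self._junction({"s1": 9}),
            self._junction({"s1": 1}),
            self._junction({"s1": 5}),
        ]
        assert filter_junctions(js) == [js[0], js[2]]


class TestContext:
    def _j(self, start, end, strand="+"):
        return BackspliceJunction(GenomicInterval("chr1", start, end, strand))

    def test_both_exonic_same_gene(self, toy_annotation):
        j = classify_context(self._j(1000, 2400), toy_annotation)
        assert j.context == ("exonic", "exonic")
        assert j.host_gene == "GA" and j.context_label == "exonic"

    def test_intergenic_both_sides(self, toy_annotation):
        j = classify_context(self._j(3500, 4500), toy_annotation)
        assert j.context == ("intergenic", "intergenic")
        assert j.host_gene is None

    def test_mixed_exonic_intronic_same_gene(self, toy_annotation):
        # end boundary at 1700-1 = 1699 sits in GA's first intron
        j = classify_context(self._j(1000, 1700), toy_annotation)
        assert j.context == ("exonic", "intronic")
        assert j.host_gene == "GA" and j.context_label == "mixed"

    def test_context_fractions_requires_classification(self):
        with pytest.raises(ValidationError):
            context_fractions([self._j(1, 2)])


class TestPositionalBias:
    def test_cds_only_junction(self, toy_annotation):
        j = BackspliceJunction(GenomicInterval("chr1", 2000, 2400, "+"))
        bias = positional_bias([j], toy_annotation)
        assert bias == {"CDS": 1.0, "UTR5": 0.0, "UTR3": 0.0}

    def test_utr5_cds_spanning_counts_in_both(self, toy_annotation):
        j = BackspliceJunction(GenomicInterval("chr1", 1100, 1300, "+"))
        bias = positional_bias([j], toy_annotation)
        assert bias["CDS"] == 1.0 and bias["UTR5"] == 1.0 and bias["UTR3"] == 0.0

    def test_empty_input_rejected(self, toy_annotation):
        with pytest.raises(ValidationError):
            positional_bias([], toy_annotation)

    def test_fractions_match_bruteforce(self, toy_annotation, rng):
        junctions = [
            BackspliceJunction(
                GenomicInterval("chr1", int(s), int(s) + int(l), "+")
            )
            for s, l in zip(
                rng.integers(900, 7000, size=10), rng.integers(50, 800, size=10)
            )
        ]
        bias = positional_bias(junctions, toy_annotation)
        regions = {
            "CDS": toy_annotation.cds_regions,
            "UTR5": toy_annotation.utr5_regions,
            "UTR3": toy_annotation.utr3_regions,
        }
        for cls, store in regions.items():
            n = 0
            for j in junctions:
                ivs = [iv for gene_ivs in store.values() for iv in gene_ivs]
                if any(j.interval.overlaps(iv) for iv in ivs):
                    n += 1
            assert bias[cls] == pytest.approx(n / len(junctions))


class TestRecovery:
    def test_spiked_junctions_recovered_by_call_and_filter(self, sim_annotation):
        """Junctions with expected per-sample support >= 8 reads survive the
        default >=4-in-one-sample filter essentially always."""
        from circgrade.synthetic import SpikeConfig, generate_cohort

        missed = total = 0
        for seed in range(3):
            cohort = generate_cohort(
                sim_annotation, n_junctions=150,
                spike=SpikeConfig(n_spiked=30, effect_size=1.0), seed=50 + seed,
            )
            called = filter_junctions(call_backsplices(cohort.chimeric))
            called_keys = {j.key for j in called}
            truth = cohort.truth
            mean_count = cohort.circ_counts.counts.mean(axis=1)
            strong = truth[
                truth.is_spiked.to_numpy()
                & (mean_count.reindex(truth.feature_id).to_numpy() >= 8)
            ]
            for row in strong.itertuples(index=False):
                total += 1
                if (row.chrom, row.start, row.end, row.strand) not in called_keys:
                    missed += 1
        assert total > 20
        assert missed / total < 0.01


def test_summarize_candidates_ratio():
    js = []
    for i in range(5):
        j = BackspliceJunction(GenomicInterval("chr1", 10 * i + 1, 10 * i + 5))
        j.host_gene = f"G{i % 3}"
        js.append(j)
    summary = summarize_candidates(js)
    assert summary["n_candidates"] == 5
    assert summary["n_host_genes"] == 3
    assert summary["candidates_per_gene"] == round(5 / 3, 2)
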