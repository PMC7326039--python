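"""Synthetic cohort generator with known ground truth.

Emulates a 58-sample bladder-cancer cohort (grades G1/G2/G3 = 17/5/36 by
default, six of the G3 samples muscle-invasive) producing every artifact
the pipeline consumes: a gene annotation, chimeric junction records, linear
splice-boundary counts, a sample table, a miRNA site table and external
reference cohorts — all pure functions of (config, seed).

Count model: negative binomial with marginal dispersion 0.3 (variance
m + d*m^2), the standard overdispersed RNA-seq choice. The circular and
linear reads of one junction in one sample share a latent host-expression
factor (gamma, mean 1): biologically, back-spliced and linearly spliced
reads are transcribed from the same locus, so their biological variation
is common — which is precisely why the circular-to-linear ratio is a
useful statistic (the shared factor cancels in the ratio). Conditional on
the factor, counts are NB with a small residual dispersion
(``residual_dispersion``, default 0.05); the factor's variance is set so
the marginal dispersion of every count equals ``dispersion``. Simulated
depth defaults to ~10^6 reads per sample rather than tens of millions;
CPM normalization makes downstream results scale-free, so this only
trades read-level granularity for speed.

The grade effect is injected on the log2 circular-to-linear ratio: in the
affected grades a spiked junction's circular mean is rescaled on the
(CPM + 1) scale so that the true relative-expression difference between
affected and unaffected grades equals ``effect_size`` log2 units exactly.
Linear counts never carry a grade effect, so differential-relative-
expression truth is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationDB, GeneRecord
from .backsplice import BackspliceJunction, ChimericRecord
from .errors import ConfigurationError
from .intervals import GenomicInterval
from .quantify import CountMatrix

DEFAULT_CONTEXT_MIX = {"exonic": 0.94, "intronic": 0.04, "intergenic": 0.02}


@dataclass(frozen=True)
class SamplePlan:
    """Per-grade sample counts and sequencing depth of the simulated cohort."""

    n_g1: int = 17
    n_g2: int = 5
    n_g3: int = 36
    n_mibc: int = 6  # subset of the G3 samples labelled muscle-invasive
    mean_library_size: int = 1_000_000
    library_size_cv: float = 0.2

    def __post_init__(self):
        if min(self.n_g1, self.n_g2, self.n_g3) < 0:
            raise ConfigurationError("negative sample count")
        if self.n_mibc > self.n_g3:
            raise ConfigurationError("n_mibc exceeds the G3 sample count")
        if self.mean_library_size <= 0:
            raise ConfigurationError("mean_library_size must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_g1 + self.n_g2 + self.n_g3


@dataclass(frozen=True)
class SpikeConfig:
    """Junctions with a grade-dependent circular-to-linear shift.

    ``effect_size`` is the additive shift of the true log2 relative
    expression in the affected grades; ``direction`` is ``up``, ``down`` or
    ``both`` (random sign per junction).
    """

    n_spiked: int = 0
    effect_size: float = 0.0
    direction: str = "both"
    affected_grades: tuple[str, ...] = ("G3",)

    def __post_init__(self):
        if self.n_spiked < 0:
            raise ConfigurationError("n_spiked must be >= 0")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.direction not in ("up", "down", "both"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")


@dataclass
class SyntheticCohort:
    """Everything one simulated cohort produced, plus its ground truth."""

    samples: pd.DataFrame
    truth: pd.DataFrame
    circ_counts: CountMatrix
    linear_table: pd.DataFrame
    chimeric: list[ChimericRecord] | None

    def write(self, outdir) -> None:
        from . import formats

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        formats.write_sample_table(self.samples, outdir / "samples.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        formats.write_count_matrix(
            self.circ_counts.counts, outdir / "circ_counts.tsv"
        )
        formats.write_linear_table(self.linear_table, outdir / "linear.tsv")
        if self.chimeric is not None:
            formats.write_chimeric_table(self.chimeric, outdir / "chimeric.tsv")


def _nb(rng: np.random.Generator, mean, dispersion: float):
    """Negative binomial draws with mean *mean* and var = m + d*m^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    seed: int,
    n_genes: int = 200,
    exons_per_gene_range: tuple[int, int] = (2, 8),
    chrom_count: int = 5,
    chrom_length: int = 20_000_000,
) -> AnnotationDB:
    """Simulate non-overlapping genes with exon structure and UTR/CDS splits.

    Genes are packed left to right on ``chrom_count`` chromosomes
    (``chrS1..chrSn``) with random intergenic gaps. Each gene's mature
    (exonic) sequence is partitioned in transcription order into 5'UTR
    (~15%), CDS and 3'UTR (~20%), each at least 1 bp, split across exons
    where the boundaries fall inside an exon.
    """
    if n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    lo, hi = exons_per_gene_range
    if lo < 1 or hi < lo:
        raise ConfigurationError("bad exons_per_gene_range")
    rng = np.random.default_rng(seed)
    chroms = [f"chrS{i + 1}" for i in range(chrom_count)]
    cursor = {c: 1000 for c in chroms}

    genes: list[GeneRecord] = []
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    utr5: dict[str, list[GenomicInterval]] = {}
    utr3: dict[str, list[GenomicInterval]] = {}

    for i in range(n_genes):
        gene_id = f"SG{i + 1:05d}"
        chrom = chroms[i % chrom_count]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(lo, hi + 1))
        exon_lens = rng.integers(120, 400, size=n_exons)
        intron_lens = (
            rng.integers(300, 2000, size=n_exons - 1) if n_exons > 1 else []
        )
        start = cursor[chrom] + int(rng.integers(1_000, 10_000))
        pos = start
        gene_exons = []
        for k in range(n_exons):
            gene_exons.append(
                GenomicInterval(chrom, pos, pos + int(exon_lens[k]), strand)
            )
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        gene_end = pos
        if gene_end > chrom_length:
            raise ConfigurationError(
                f"infeasible packing: gene {gene_id} would end at {gene_end} "
                f"> chromosome length {chrom_length}"
            )
        cursor[chrom] = gene_end
        genes.append(
            GeneRecord(
                gene_id, gene_id, GenomicInterval(chrom, start, gene_end, strand)
            )
        )
        exons[gene_id] = gene_exons
        u5, c, u3 = _partition_mature(gene_exons, strand)
        utr5[gene_id], cds[gene_id], utr3[gene_id] = u5, c, u3

    db = AnnotationDB(
        genes=genes, exons=exons, cds_regions=cds,
        utr5_regions=utr5, utr3_regions=utr3,
    )
    db.validate()
    return db


def _partition_mature(gene_exons, strand):
    """Split the exon chain into 5'UTR / CDS / 3'UTR in transcription order."""
    total = sum(len(e) for e in gene_exons)
    n5 = max(1, round(0.15 * total))
    n3 = max(1, round(0.20 * total))
    if n5 + n3 >= total:  # tiny gene: 1 bp UTRs
        n5 = n3 = 1
    ncds = total - n5 - n3
    order = gene_exons if strand == "+" else list(reversed(gene_exons))
    spans = {"UTR5": [], "CDS": [], "UTR3": []}
    budget = [("UTR5", n5), ("CDS", ncds), ("UTR3", n3)]
    bi = 0
    for exon in order:
        exon_left = len(exon)
        # walk the exon in transcription direction, peeling region budgets
        offset = 0
        while exon_left > 0:
            cls, remaining = budget[bi]
            take = min(exon_left, remaining)
            if strand == "+":
                s = exon.start + offset
                spans[cls].append(
                    GenomicInterval(exon.chrom, s, s + take, strand)
                )
            else:
                e = exon.end - offset
                spans[cls].append(
                    GenomicInterval(exon.chrom, e - take, e, strand)
                )
            offset += take
            exon_left -= take
            remaining -= take
            budget[bi] = (cls, remaining)
            if remaining == 0 and bi < len(budget) - 1:
                bi += 1
    return (
        sorted(spans["UTR5"], key=lambda iv: iv.start),
        sorted(spans["CDS"], key=lambda iv: iv.start),
        sorted(spans["UTR3"], key=lambda iv: iv.start),
    )


# ---------------------------------------------------------------------------
# cohort


def generate_sample_table(plan: SamplePlan, rng: np.random.Generator) -> pd.DataFrame:
    grades = ["G1"] * plan.n_g1 + ["G2"] * plan.n_g2 + ["G3"] * plan.n_g3
    stages = ["NMIBC"] * (plan.n_samples - plan.n_mibc) + ["MIBC"] * plan.n_mibc
    sigma = math.sqrt(math.log(1 + plan.library_size_cv**2))
    mu = math.log(plan.mean_library_size) - sigma**2 / 2
    libs = np.maximum(
        10_000, rng.lognormal(mu, sigma, size=plan.n_samples).astype(np.int64)
    )
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:02d}" for i in range(plan.n_samples)],
            "grade": grades,
            "stage_class": stages,
            "library_size": libs,
        }
    )


def generate_cohort(
    annotation: AnnotationDB,
    sample_plan: SamplePlan | None = None,
    n_junctions: int = 2000,
    spike: SpikeConfig | None = None,
    seed: int = 0,
    context_mix: dict[str, float] | None = None,
    dispersion: float = 0.3,
    residual_dispersion: float = 0.05,
    noise_record_fraction: float = 0.01,
    with_chimeric: bool = True,
    layout_seed: int | None = None,
) -> SyntheticCohort:
    """Simulate one cohort: junction coordinates, counts and ground truth.

    Junction genomic contexts follow *context_mix* (default 94% exonic, 4%
    intronic, 2% intergenic). Per-sample circular and linear boundary
    counts are negative binomial around junction baselines scaled by the
    sample's library size and by a shared latent host-expression factor
    (see the module docstring); the marginal dispersion of each count is
    *dispersion*. When ``with_chimeric`` is set, one chimeric record per
    circular read is materialized (plus a small fraction of non-qualifying
    noise records); the drawn counts are identical either way.

    ``layout_seed`` fixes the cohort's underlying biology — junction
    coordinates, baseline abundances and which junctions are spiked —
    independently of *seed*, which then only drives sampling noise. Two
    calls sharing a layout_seed but differing in seed emulate two cohorts
    drawn from the same grade-effect truth.
    """
    plan = sample_plan or SamplePlan()
    spike = spike or SpikeConfig()
    mix = context_mix or DEFAULT_CONTEXT_MIX
    if spike.n_spiked > n_junctions:
        raise ConfigurationError("n_spiked exceeds n_junctions")
    if n_junctions < 1:
        raise ConfigurationError("n_junctions must be >= 1")
    rng = np.random.default_rng(seed)
    rng_layout = (
        rng if layout_seed is None else np.random.default_rng(layout_seed)
    )
    samples = generate_sample_table(plan, rng)
    junctions = _place_junctions(annotation, n_junctions, mix, rng_layout)

    n_s = plan.n_samples
    grades = samples["grade"].to_numpy()
    libs = samples["library_size"].to_numpy(dtype=float)
    scale = libs / plan.mean_library_size
    ref_lib = float(plan.mean_library_size)

    # junction baselines (counts at the reference library size)
    mu_circ = rng_layout.lognormal(math.log(10.0), 0.7, size=n_junctions)
    mu_lin_left = rng_layout.lognormal(math.log(40.0), 0.8, size=n_junctions)
    mu_lin_right = rng_layout.lognormal(math.log(40.0), 0.8, size=n_junctions)

    # spike assignment
    is_spiked = np.zeros(n_junctions, dtype=bool)
    signs = np.zeros(n_junctions)
    if spike.n_spiked:
        idx = rng_layout.choice(n_junctions, size=spike.n_spiked, replace=False)
        is_spiked[idx] = True
        if spike.direction == "up":
            signs[idx] = 1.0
        elif spike.direction == "down":
            signs[idx] = -1.0
        else:
            signs[idx] = rng_layout.choice([-1.0, 1.0], size=spike.n_spiked)

    # per-grade circular means on the (CPM + 1) scale so the true relative
    # expression shifts by exactly +/- effect_size in affected grades
    cpm_circ = mu_circ / ref_lib * 1e6
    affected = np.isin(grades, spike.affected_grades)
    fold = np.power(2.0, signs * spike.effect_size)
    cpm_circ_affected = np.maximum(0.0, fold * (cpm_circ + 1.0) - 1.0)

    mean_circ = np.empty((n_junctions, n_s))
    base_counts = mu_circ[:, None] * scale[None, :]
    aff_counts = (cpm_circ_affected / 1e6 * ref_lib)[:, None] * scale[None, :]
    mean_circ[:, :] = np.where(affected[None, :], aff_counts, base_counts)

    # shared host-expression factor per (junction, sample): its variance is
    # chosen so each count's marginal dispersion equals `dispersion`
    if residual_dispersion > dispersion:
        raise ConfigurationError("residual_dispersion exceeds dispersion")
    bio_var = (dispersion - residual_dispersion) / (1.0 + residual_dispersion)
    if bio_var > 0:
        factor = rng.gamma(1.0 / bio_var, bio_var, size=(n_junctions, n_s))
    else:
        factor = np.ones((n_junctions, n_s))

    circ = _nb(rng, factor * mean_circ, residual_dispersion)
    lin_left = _nb(
        rng, factor * mu_lin_left[:, None] * scale[None, :], residual_dispersion
    )
    lin_right = _nb(
        rng, factor * mu_lin_right[:, None] * scale[None, :], residual_dispersion
    )

    sample_ids = samples["sample_id"].tolist()
    feature_ids = [
        f"{j.interval.chrom}:{j.interval.start}-{j.interval.end}"
        f"({j.interval.strand})"
        for j in junctions
    ]
    circ_df = pd.DataFrame(circ, index=feature_ids, columns=sample_ids)
    lib_series = pd.Series(libs.astype(np.int64), index=sample_ids)
    circ_counts = CountMatrix(circ_df, lib_series)

    linear_rows = []
    for ji, j in enumerate(junctions):
        iv = j.interval
        for si, s in enumerate(sample_ids):
            if lin_left[ji, si] > 0:
                linear_rows.append((iv.chrom, iv.start, s, int(lin_left[ji, si])))
            if lin_right[ji, si] > 0:
                linear_rows.append((iv.chrom, iv.end, s, int(lin_right[ji, si])))
    linear_table = pd.DataFrame(
        linear_rows, columns=["chrom", "pos", "sample_id", "count"]
    )

    truth = _truth_table(
        annotation,
        junctions,
        feature_ids,
        is_spiked,
        signs,
        spike,
        cpm_circ,
        cpm_circ_affected,
        np.maximum(mu_lin_left, mu_lin_right) / ref_lib * 1e6,
        sorted(set(grades)),
    )

    chimeric = None
    if with_chimeric:
        chimeric = _emit_chimeric(
            junctions, feature_ids, circ, sample_ids, noise_record_fraction, rng
        )

    return SyntheticCohort(
        samples=samples,
        truth=truth,
        circ_counts=circ_counts,
        linear_table=linear_table,
        chimeric=chimeric,
    )


def _place_junctions(annotation, n_junctions, mix, rng) -> list[BackspliceJunction]:
    labels = list(mix)
    probs = np.array([mix[c] for c in labels], dtype=float)
    probs = probs / probs.sum()
    genes = annotation.genes
    multi_exon = [g for g in genes if len(annotation.exons[g.gene_id]) >= 2]
    # intergenic gaps per chromosome
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g)
    gaps = []
    for chrom, gs in by_chrom.items():
        gs = sorted(gs, key=lambda g: g.interval.start)
        prev = 0
        for g in gs:
            if g.interval.start - prev > 600:
                gaps.append((chrom, prev + 50, g.interval.start - 50))
            prev = g.interval.end
    if not gaps:
        gaps = [(genes[0].interval.chrom, 0, 100)]

    def propose(ctx) -> GenomicInterval | None:
        if ctx == "exonic":
            g = genes[rng.integers(0, len(genes))]
            ex = annotation.exons[g.gene_id]
            i = int(rng.integers(0, len(ex)))
            j = int(rng.integers(i, len(ex)))
            return GenomicInterval(
                ex[i].chrom, ex[i].start, ex[j].end, g.interval.strand
            )
        if ctx == "intronic":
            if not multi_exon:
                return None
            g = multi_exon[rng.integers(0, len(multi_exon))]
            ex = annotation.exons[g.gene_id]
            k = int(rng.integers(0, len(ex) - 1))
            lo, hi = ex[k].end, ex[k + 1].start
            if hi - lo < 40:
                return None
            a = int(rng.integers(lo + 1, hi - 20))
            b = int(rng.integers(a + 10, hi))
            return GenomicInterval(ex[0].chrom, a, b, g.interval.strand)
        chrom, lo, hi = gaps[rng.integers(0, len(gaps))]
        if hi - lo < 60:
            return None
        a = int(rng.integers(lo, hi - 40))
        b = int(rng.integers(a + 30, min(hi, a + 4000)))
        return GenomicInterval(chrom, a, b, "+" if rng.random() < 0.5 else "-")

    # draw every junction's context up front, then rejection-sample fresh
    # coordinates per context: collisions must not skew the context mix
    contexts = [labels[i] for i in rng.choice(len(labels), size=n_junctions, p=probs)]
    seen: set = set()
    out: list[BackspliceJunction] = []
    for ctx in contexts:
        for _attempt in range(10_000):
            iv = propose(ctx)
            if iv is None:
                continue
            key = (iv.chrom, iv.start, iv.end, iv.strand)
            if key not in seen:
                break
        else:
            raise ConfigurationError(
                f"cannot place a fresh {ctx} junction; annotation too small "
                f"for n_junctions={n_junctions}"
            )
        seen.add(key)
        out.append(BackspliceJunction(iv))
    return out


def _truth_table(
    annotation,
    junctions,
    feature_ids,
    is_spiked,
    signs,
    spike,
    cpm_circ,
    cpm_circ_affected,
    cpm_lin,
    grade_levels,
):
    from .backsplice import classify_context

    base_rel = np.log2((cpm_circ + 1.0) / (cpm_lin + 1.0))
    aff_rel = np.log2((cpm_circ_affected + 1.0) / (cpm_lin + 1.0))
    rows = []
    for i, (fid, j) in enumerate(zip(feature_ids, junctions)):
        classified = classify_context(j, annotation)
        row = {
            "feature_id": fid,
            "chrom": j.interval.chrom,
            "start": j.interval.start,
            "end": j.interval.end,
            "strand": j.interval.strand,
            "context": classified.context_label,
            "host_gene": classified.host_gene,
            "is_spiked": bool(is_spiked[i]),
            "direction": (
                "up" if signs[i] > 0 else "down" if signs[i] < 0 else "none"
            ),
        }
        for g in grade_levels:
            rel = aff_rel[i] if g in spike.affected_grades else base_rel[i]
            row[f"true_mean_{g}"] = rel
        rows.append(row)
    return pd.DataFrame(rows)


def _emit_chimeric(
    junctions, feature_ids, circ, sample_ids, noise_fraction, rng
) -> list[ChimericRecord]:
    records: list[ChimericRecord] = []
    for ji, j in enumerate(junctions):
        iv = j.interval
        if iv.strand == "+":
            donor = (iv.chrom, iv.end, "+")
            acceptor = (iv.chrom, iv.start, "+")
        else:
            donor = (iv.chrom, iv.start, "-")
            acceptor = (iv.chrom, iv.end, "-")
        for si, s in enumerate(sample_ids):
            for k in range(int(circ[ji, si])):
                records.append(
                    ChimericRecord(
                        sample_id=s,
                        donor=donor,
                        acceptor=acceptor,
                        read_id=f"r{ji}.{s}.{k}",
                    )
                )
    n_noise = int(round(noise_fraction * len(records)))
    chroms = sorted({j.interval.chrom for j in junctions})
    for k in range(n_noise):
        # linear-orientation split reads: skipped by the caller
        chrom = chroms[rng.integers(0, len(chroms))]
        pos = int(rng.integers(1000, 1_000_000))
        records.append(
            ChimericRecord(
                sample_id=sample_ids[int(rng.integers(0, len(sample_ids)))],
                donor=(chrom, pos, "+"),
                acceptor=(chrom, pos + int(rng.integers(100, 5000)), "+"),
                read_id=f"noise.{k}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# miRNA sites


def generate_site_table(
    annotation: AnnotationDB,
    n_sites: int,
    frac_long: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate a conserved miRNA family target-site table.

    Sites have length 7 or 8 bp except exactly ``round(frac_long *
    n_sites)`` long sites (9-12 bp); every site is placed inside a
    simulated gene body. Columns: chrom, start (0-based), end,
    mirna_family, gene_symbol.
    """
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    if not 0 <= frac_long <= 1:
        raise ConfigurationError("frac_long must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_long = round(frac_long * n_sites)
    lengths = np.empty(n_sites, dtype=np.int64)
    lengths[:n_sites - n_long] = rng.choice([7, 8], size=n_sites - n_long)
    lengths[n_sites - n_long:] = rng.integers(9, 13, size=n_long)
    lengths = rng.permutation(lengths)

    genes = annotation.genes
    gidx = rng.integers(0, len(genes), size=n_sites)
    starts = np.empty(n_sites, dtype=np.int64)
    chroms = np.empty(n_sites, dtype=object)
    symbols = np.empty(n_sites, dtype=object)
    gstart = np.array([g.interval.start for g in genes])
    gend = np.array([g.interval.end for g in genes])
    span = gend[gidx] - gstart[gidx] - lengths
    starts = gstart[gidx] + (rng.random(n_sites) * np.maximum(1, span)).astype(
        np.int64
    )
    chroms = np.array([genes[i].interval.chrom for i in gidx], dtype=object)
    symbols = np.array([genes[i].name for i in gidx], dtype=object)
    families = np.array(
        [f"miR-{i}" for i in rng.integers(1, 1000, size=n_sites)], dtype=object
    )
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "mirna_family": families,
            "gene_symbol": symbols,
        }
    )


# ---------------------------------------------------------------------------
# reference cohorts


def generate_reference_cohort(
    junction_keys,
    match_fraction: float,
    coordinate_offset: int,
    seed: int,
    n_novel: int | None = None,
) -> pd.DataFrame:
    """Simulate an external cohort's circRNA list.

    ``round(match_fraction * n)`` entries copy input junctions with the
    start shifted by *coordinate_offset* (0 for a 0-based source, +1 for a
    1-based one); the remaining entries (defaulting to the complement of
    the matches) are novel intervals guaranteed not to match any input key
    after unification. Columns: chrom, start, end.
    """
    junction_keys = list(junction_keys)
    if not junction_keys:
        raise ConfigurationError("empty junction list")
    if not 0 <= match_fraction <= 1:
        raise ConfigurationError("match_fraction must lie in [0, 1]")
    if coordinate_offset not in (0, 1):
        raise ConfigurationError("coordinate_offset must be 0 or +1")
    rng = np.random.default_rng(seed)
    n = len(junction_keys)
    n_match = round(match_fraction * n)
    if n_novel is None:
        n_novel = n - n_match
    pick = rng.choice(n, size=n_match, replace=False)
    key_set = set(junction_keys)
    rows = [
        (
            junction_keys[i][0],
            junction_keys[i][1] + coordinate_offset,
            junction_keys[i][2],
        )
        for i in sorted(pick)
    ]
    chroms = sorted({k[0] for k in junction_keys})
    made = 0
    while made < n_novel:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, 5_000_000))
        end = start + int(rng.integers(100, 4000))
        if (chrom, start, end) in key_set:
            continue
        rows.append((chrom, start + coordinate_offset, end))
        made += 1
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# gene expression (for the gene-level stand-in and pathway analysis)


def generate_gene_counts(
    annotation: AnnotationDB,
    samples: pd.DataFrame,
    seed: int,
    de_fraction: float = 0.1,
    effect_size: float = 1.0,
    affected_grades: tuple[str, ...] = ("G3",),
    dispersion: float = 0.3,
    mean_library_size: float | None = None,
) -> tuple[CountMatrix, set[str]]:
    """Simulate gene-level counts with a grade effect in a gene subset.

    Returns the CountMatrix and the set of truly differential gene ids
    (fold change 2^effect_size in the affected grades, random sign).
    """
    rng = np.random.default_rng(seed)
    gene_ids = annotation.gene_ids
    n_g = len(gene_ids)
    libs = samples.set_index("sample_id")["library_size"].astype(float)
    ref = mean_library_size or float(libs.mean())
    scale = (libs / ref).to_numpy()
    grades = samples.set_index("sample_id")["grade"].to_numpy()

    mu = rng.lognormal(math.log(60.0), 1.0, size=n_g)
    n_de = int(round(de_fraction * n_g))
    de_idx = rng.choice(n_g, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    fold = np.ones(n_g)
    fold[de_idx] = np.power(2.0, signs * effect_size)
    affected = np.isin(grades, affected_grades)
    mean = mu[:, None] * scale[None, :]
    mean = np.where(affected[None, :], mean * fold[:, None], mean)
    counts = _nb(rng, mean, dispersion)
    df = pd.DataFrame(counts, index=gene_ids, columns=samples["sample_id"])
    cm = CountMatrix(df, pd.Series(libs.to_numpy(), index=samples["sample_id"]))
    return cm, {gene_ids[i] for i in de_idx}
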