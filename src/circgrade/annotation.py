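"""Gene annotation container with interval indexes.

The annotation model is deliberately small: genes with exon structure and a
partition of the mature transcript into 5'UTR, CDS and 3'UTR. That is all
the genomic-context classification and the positional-bias summary need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree

from .errors import ValidationError
from .intervals import GenomicInterval

REGION_CLASSES = ("CDS", "UTR5", "UTR3")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    name: str
    interval: GenomicInterval


@dataclass
class AnnotationDB:
    """Genes plus per-gene exon/CDS/UTR intervals, indexed for queries.

    Invariants checked on :meth:`validate`: every feature interval lies
    inside its gene; CDS and UTR regions of a gene do not overlap each other.
    """

    genes: list[GeneRecord] = field(default_factory=list)
    exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    cds_regions: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    utr5_regions: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    utr3_regions: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self):
        self._gene_by_id = {g.gene_id: g for g in self.genes}
        self._gene_tree: dict[str, IntervalTree] = {}
        self._exon_tree: dict[str, IntervalTree] = {}
        self._region_tree: dict[str, dict[str, IntervalTree]] = {
            c: {} for c in REGION_CLASSES
        }
        for g in self.genes:
            iv = g.interval
            self._gene_tree.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, g.gene_id
            )
        for gene_id, ivs in self.exons.items():
            for iv in ivs:
                self._exon_tree.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, gene_id
                )
        for cls, regions in (
            ("CDS", self.cds_regions),
            ("UTR5", self.utr5_regions),
            ("UTR3", self.utr3_regions),
        ):
            for gene_id, ivs in regions.items():
                for iv in ivs:
                    self._region_tree[cls].setdefault(
                        iv.chrom, IntervalTree()
                    ).addi(iv.start, iv.end, gene_id)

    # -- queries -----------------------------------------------------------

    def gene(self, gene_id: str) -> GeneRecord:
        return self._gene_by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        """Gene ids whose body contains the 0-based position."""
        tree = self._gene_tree.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.at(pos)}

    def exon_genes_at(self, chrom: str, pos: int) -> set[str]:
        """Gene ids with an exon containing the 0-based position."""
        tree = self._exon_tree.get(chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.at(pos)}

    def region_overlaps(self, region_class: str, interval: GenomicInterval) -> bool:
        """True if *interval* shares >=1 bp with any region of the class."""
        if region_class not in REGION_CLASSES:
            raise ValidationError(f"unknown region class {region_class!r}")
        tree = self._region_tree[region_class].get(interval.chrom)
        if tree is None:
            return False
        return bool(tree.overlap(interval.start, interval.end))

    # -- consistency -------------------------------------------------------

    def validate(self) -> None:
        for gene_id, ivs in list(self.exons.items()) + list(
            self.cds_regions.items()
        ) + list(self.utr5_regions.items()) + list(self.utr3_regions.items()):
            gene = self._gene_by_id.get(gene_id)
            if gene is None:
                raise ValidationError(f"feature for unknown gene {gene_id}")
            for iv in ivs:
                if not gene.interval.contains(iv):
                    raise ValidationError(
                        f"feature {iv} escapes gene {gene_id} body"
                    )
        for gene_id in self._gene_by_id:
            regions: list[tuple[str, GenomicInterval]] = []
            for cls, store in (
                ("CDS", self.cds_regions),
                ("UTR5", self.utr5_regions),
                ("UTR3", self.utr3_regions),
            ):
                regions += [(cls, iv) for iv in store.get(gene_id, [])]
            for i, (ca, a) in enumerate(regions):
                for cb, b in regions[i + 1 :]:
                    if a.overlaps(b):
                        raise ValidationError(
                            f"{ca} and {cb} regions overlap in gene {gene_id}"
                        )

    def iter_features(self) -> Iterable[tuple[str, str, str, GenomicInterval]]:
        """Yield (feature_type, gene_id, gene_name, interval) rows.

        Ordered gene by gene: gene record first, then exons, CDS, UTRs.
        """
        type_map = {
            "CDS": self.cds_regions,
            "five_prime_utr": self.utr5_regions,
            "three_prime_utr": self.utr3_regions,
        }
        for g in self.genes:
            yield "gene", g.gene_id, g.name, g.interval
            for iv in self.exons.get(g.gene_id, []):
                yield "exon", g.gene_id, g.name, iv
            for ftype, store in type_map.items():
                for iv in store.get(g.gene_id, []):
                    yield ftype, g.gene_id, g.name, iv
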