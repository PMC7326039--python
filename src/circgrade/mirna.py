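"""miRNA target-site filtering and containment within circRNA intervals.

Circular RNAs can act as miRNA sponges: transcripts carrying target sites
that sequester miRNAs. The analysis here is purely coordinate-based — a
conserved-family site table is filtered to canonical 7/8-bp seed-match
sites, then each site is tested for full containment within a circle's
genomic span. Strand is ignored by default (the coordinate-level procedure
is strand-blind); ``stranded=True`` requires matching strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .errors import ValidationError

SITE_COLUMNS = ["chrom", "start", "end", "mirna_family", "gene_symbol"]

CANONICAL_LENGTHS = (7, 8)


@dataclass(frozen=True)
class SiteFilterResult:
    sites: pd.DataFrame
    n_input: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0

    @property
    def retained_percent(self) -> float:
        """Retention as a percentage rounded to two decimals."""
        return round(100.0 * self.retained_fraction, 2)


def site_lengths(sites: pd.DataFrame) -> pd.Series:
    lengths = sites["end"] - sites["start"]
    if (lengths < 6).any():
        raise ValidationError("site shorter than 6 bp")
    return lengths


def filter_sites(sites: pd.DataFrame) -> SiteFilterResult:
    """Keep sites of length 7 or 8 bp; drop everything else.

    Returns the filtered table together with the retention fraction, the
    headline quality number for a conserved-site table.
    """
    lengths = site_lengths(sites)
    keep = lengths.isin(CANONICAL_LENGTHS)
    return SiteFilterResult(
        sites=sites.loc[keep].reset_index(drop=True),
        n_input=len(sites),
        n_retained=int(keep.sum()),
    )


def overlap_sites(
    circles, sites: pd.DataFrame, stranded: bool = False
) -> pd.DataFrame:
    """Sites fully contained within circle intervals.

    A pair (circle, site) is emitted iff the site interval lies entirely
    inside the circle span on the same chromosome; each pair at most once.
    Sites in introns internal to an exonic circle still count — the match is
    genomic, not transcript-level.

    Returns a DataFrame with columns circle_id, chrom, circle_start,
    circle_end, site_start, site_end, mirna_family, gene_symbol.
    """
    trees: dict = {}
    circle_info = {}
    for c in circles:
        iv = c.interval
        cid = f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"
        key = iv.chrom if not stranded else (iv.chrom, iv.strand)
        trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end, cid)
        circle_info[cid] = iv
    if stranded and "strand" not in sites.columns:
        raise ValidationError("stranded matching needs a site strand column")
    rows = []
    for tup in sites.itertuples(index=False):
        key = tup.chrom if not stranded else (tup.chrom, tup.strand)
        tree = trees.get(key)
        if tree is None:
            continue
        for hit in tree.overlap(tup.start, tup.end):
            if hit.begin <= tup.start and tup.end <= hit.end:
                rows.append(
                    {
                        "circle_id": hit.data,
                        "chrom": tup.chrom,
                        "circle_start": hit.begin,
                        "circle_end": hit.end,
                        "site_start": tup.start,
                        "site_end": tup.end,
                        "mirna_family": tup.mirna_family,
                        "gene_symbol": getattr(tup, "gene_symbol", None),
                    }
                )
    cols = [
        "circle_id",
        "chrom",
        "circle_start",
        "circle_end",
        "site_start",
        "site_end",
        "mirna_family",
        "gene_symbol",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.drop_duplicates(
        subset=["circle_id", "chrom", "site_start", "site_end", "mirna_family"]
    ).reset_index(drop=True)


@dataclass
class SpongeSummary:
    n_circles: int
    n_host_genes: int
    n_mirna_families: int
    host_table: pd.DataFrame
    recurrence: pd.DataFrame


def summarize_sponges(
    pairs: pd.DataFrame, hosts, de_circles=None, genes_de=None
) -> SpongeSummary:
    """Summarize site-carrying circles per host gene and per miRNA family.

    *hosts* maps circle_id -> host gene (None allowed). Recurrence is the
    number of distinct circles carrying each miRNA family, ranked
    descending with alphabetical tie-break. Hosts appearing both among the
    DE circles' hosts and in the gene-level DE set are flagged
    ``de_both_levels``.
    """
    hosts = dict(hosts)
    de_circles = set(de_circles or ())
    genes_de = set(genes_de or ())
    if pairs.empty:
        return SpongeSummary(
            0,
            0,
            0,
            host_table=pd.DataFrame(
                columns=["host_gene", "n_circles", "n_families", "de_both_levels"]
            ),
            recurrence=pd.DataFrame(columns=["mirna_family", "n_circles"]),
        )
    circles = pairs["circle_id"].unique()
    circle_hosts = {c: hosts.get(c) for c in circles}
    host_genes = {h for h in circle_hosts.values() if h is not None}

    rec = (
        pairs.groupby("mirna_family")["circle_id"]
        .nunique()
        .rename("n_circles")
        .reset_index()
        .sort_values(
            ["n_circles", "mirna_family"], ascending=[False, True]
        )
        .reset_index(drop=True)
    )

    de_hosts = {hosts.get(c) for c in de_circles if hosts.get(c) is not None}
    rows = []
    by_host: dict = {}
    for c in circles:
        h = circle_hosts[c]
        if h is not None:
            by_host.setdefault(h, []).append(c)
    for h in sorted(by_host):
        sub = pairs[pairs["circle_id"].isin(by_host[h])]
        rows.append(
            {
                "host_gene": h,
                "n_circles": sub["circle_id"].nunique(),
                "n_families": sub["mirna_family"].nunique(),
                "de_both_levels": h in de_hosts and h in genes_de,
            }
        )
    return SpongeSummary(
        n_circles=len(circles),
        n_host_genes=len(host_genes),
        n_mirna_families=pairs["mirna_family"].nunique(),
        host_table=pd.DataFrame(rows),
        recurrence=rec,
    )
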