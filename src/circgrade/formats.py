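"""Readers and writers for every on-disk artifact the pipeline touches.

Dialects
--------
chimeric table
    TSV with header ``sample_id chrom_donor pos_donor strand_donor
    chrom_acceptor pos_acceptor strand_acceptor read_id``; positions are
    1-based in the file and shifted to the internal 0-based convention on
    read (and back on write).
BED
    BED3/BED6, already 0-based half-open; passed through bit-exactly.
GTF-lite
    Standard 9-column GTF restricted to features ``gene, exon, CDS,
    five_prime_utr, three_prime_utr`` with ``gene_id``/``gene_name``
    attributes; starts are 1-based inclusive in the file.
linear junction counts
    Long TSV ``chrom pos sample_id count`` with 0-based boundary positions.
count matrix
    TSV, feature rows x sample columns, first column ``feature_id``.
sample table
    TSV ``sample_id grade stage_class library_size``.
GMT
    Tab-separated ``name description gene1 gene2 ...``.

Each reader applies its dialect's coordinate offset exactly once; internal
code never adjusts offsets again.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .annotation import AnnotationDB, GeneRecord
from .backsplice import ChimericRecord
from .errors import ParseError, ValidationError
from .intervals import GenomicInterval
from .pathway import PathwayGeneSet

CHIMERIC_COLUMNS = [
    "sample_id",
    "chrom_donor",
    "pos_donor",
    "strand_donor",
    "chrom_acceptor",
    "pos_acceptor",
    "strand_acceptor",
    "read_id",
]

GTF_FEATURES = ("gene", "exon", "CDS", "five_prime_utr", "three_prime_utr")
GRADES = ("G1", "G2", "G3")
STAGE_CLASSES = ("NMIBC", "MIBC")


# ---------------------------------------------------------------------------
# chimeric junction records


def read_chimeric_table(path) -> list[ChimericRecord]:
    """Read a chimeric junction table; 1-based file positions become 0-based."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty chimeric table", path)
        if header != CHIMERIC_COLUMNS:
            raise ParseError(
                f"unexpected chimeric header {header!r}", path, line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CHIMERIC_COLUMNS):
                raise ParseError(
                    f"expected {len(CHIMERIC_COLUMNS)} fields, got {len(row)}",
                    path,
                    line=lineno,
                )
            (sid, dch, dpos, dstr, ach, apos, astr, rid) = row
            try:
                dpos_i, apos_i = int(dpos), int(apos)
            except ValueError:
                raise ParseError(
                    f"non-numeric position ({dpos!r}, {apos!r})", path, line=lineno
                )
            for s in (dstr, astr):
                if s not in ("+", "-"):
                    raise ParseError(
                        f"unknown strand symbol {s!r}", path, line=lineno
                    )
            if dpos_i < 1 or apos_i < 1:
                raise ParseError(
                    "1-based position < 1", path, line=lineno
                )
            records.append(
                ChimericRecord(
                    sample_id=sid,
                    donor=(dch, dpos_i - 1, dstr),
                    acceptor=(ach, apos_i - 1, astr),
                    read_id=rid,
                )
            )
    return records


def write_chimeric_table(records, path) -> None:
    """Write chimeric records, converting internal 0-based back to 1-based."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CHIMERIC_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.sample_id,
                    r.donor[0],
                    r.donor[1] + 1,
                    r.donor[2],
                    r.acceptor[0],
                    r.acceptor[1] + 1,
                    r.acceptor[2],
                    r.read_id,
                ]
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path, strip_chr_prefix: bool = False):
    """Read BED3+ into ``(GenomicInterval, name, score)`` tuples.

    BED is already 0-based half-open, so coordinates pass through unchanged.
    ``strip_chr_prefix`` optionally removes a leading ``chr`` from
    chromosome names; by default names are kept verbatim.
    """
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("BED line has <3 fields", path, line=lineno)
            chrom = parts[0]
            if strip_chr_prefix and chrom.startswith("chr"):
                chrom = chrom[3:]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError("non-numeric BED coordinate", path, line=lineno)
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValidationError as exc:
                raise ValidationError(f"{exc} ({path}:{lineno})")
            entries.append((iv, name, score))
    return entries


def write_bed(entries, path) -> None:
    """Write ``(interval, name, score)`` tuples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in entries:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> list[PathwayGeneSet]:
    """Read GMT gene sets; duplicate members deduplicated, order preserved."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    "GMT line needs name, description and >=1 gene",
                    path,
                    line=lineno,
                )
            name, description = parts[0], parts[1]
            members = [g for g in parts[2:] if g]
            if not members:
                raise ParseError("empty member list", path, line=lineno)
            sets.append(
                PathwayGeneSet(
                    name=name,
                    description=description,
                    genes=tuple(dict.fromkeys(members)),
                )
            )
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# GTF-lite annotation


def read_gtf(path) -> AnnotationDB:
    """Read GTF-lite; 1-based inclusive file coordinates become half-open."""
    genes: list[GeneRecord] = []
    stores = {
        "exon": {},
        "CDS": {},
        "five_prime_utr": {},
        "three_prime_utr": {},
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError("GTF line needs 9 fields", path, line=lineno)
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
            if feature not in GTF_FEATURES:
                raise ParseError(
                    f"unsupported feature {feature!r}", path, line=lineno
                )
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"bad coordinates: {exc}", path, line=lineno)
            attr_map = _parse_gtf_attrs(attrs, path, lineno)
            gene_id = attr_map.get("gene_id")
            if gene_id is None:
                raise ParseError("missing gene_id attribute", path, line=lineno)
            if feature == "gene":
                genes.append(
                    GeneRecord(gene_id, attr_map.get("gene_name", gene_id), iv)
                )
            else:
                stores[feature].setdefault(gene_id, []).append(iv)
    db = AnnotationDB(
        genes=genes,
        exons=stores["exon"],
        cds_regions=stores["CDS"],
        utr5_regions=stores["five_prime_utr"],
        utr3_regions=stores["three_prime_utr"],
    )
    db.validate()
    return db


def _parse_gtf_attrs(attrs: str, path, lineno: int) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise ParseError(f"malformed attribute {chunk!r}", path, line=lineno)
        key, value = chunk.split(" ", 1)
        out[key] = value.strip().strip('"')
    return out


def write_gtf(db: AnnotationDB, path) -> None:
    with open(path, "w") as fh:
        for ftype, gene_id, gene_name, iv in db.iter_features():
            attrs = f'gene_id "{gene_id}"; gene_name "{gene_name}";'
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "circgrade",
                        ftype,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# tabular matrices and tables


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    validate_sample_table(df)
    return df


def validate_sample_table(df: pd.DataFrame) -> None:
    required = ["sample_id", "grade", "stage_class", "library_size"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"sample table missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    bad_grade = set(df["grade"]) - set(GRADES)
    if bad_grade:
        raise ValidationError(f"unknown grade labels {sorted(bad_grade)}")
    bad_stage = set(df["stage_class"]) - set(STAGE_CLASSES)
    if bad_stage:
        raise ValidationError(f"unknown stage labels {sorted(bad_stage)}")
    if (df["library_size"] <= 0).any():
        raise ValidationError("library_size must be positive")


def write_sample_table(df: pd.DataFrame, path) -> None:
    validate_sample_table(df)
    df.to_csv(path, sep="\t", index=False)


def read_count_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    if (df.values < 0).any():
        raise ValidationError("negative entry in count matrix")
    return df


def write_count_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_matrix(path) -> pd.DataFrame:
    """Read a real-valued feature x sample matrix (e.g. relative expression)."""
    return pd.read_csv(path, sep="\t", index_col="feature_id")


write_matrix = write_count_matrix


def read_linear_table(path) -> pd.DataFrame:
    """Read linear splice-boundary counts: chrom, pos (0-based), sample_id, count."""
    df = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "sample_id": str}
    )
    required = ["chrom", "pos", "sample_id", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"linear table missing columns {missing}")
    if (df["count"] < 0).any():
        raise ValidationError("negative linear count")
    return df


def write_linear_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# file validation entry point (CLI `circgrade validate`)

_VALIDATORS = {
    "chimeric": read_chimeric_table,
    "bed": read_bed,
    "gmt": read_gmt,
    "gtf": read_gtf,
    "samples": read_sample_table,
    "counts": read_count_matrix,
    "linear": read_linear_table,
}


def validate_file(path, kind: str | None = None) -> str:
    """Parse *path* with the reader for *kind* (guessed from suffix if None).

    Returns the kind on success; raises ParseError/ValidationError on any
    dialect violation.
    """
    if kind is None:
        suffix = Path(path).suffix.lower()
        guess = {".bed": "bed", ".gmt": "gmt", ".gtf": "gtf"}.get(suffix)
        if guess is None:
            raise ValidationError(
                f"cannot guess file kind from suffix {suffix!r}; pass kind"
            )
        kind = guess
    if kind not in _VALIDATORS:
        raise ValidationError(f"unknown file kind {kind!r}")
    _VALIDATORS[kind](path)
    return kind
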