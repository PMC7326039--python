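"""Circular vs linear quantification and the relative-expression statistic.

For each back-splice junction the circular read count (junction-spanning
reads) is compared with the linearly spliced read support at the same
locus. Counts are normalized to counts per million (CPM) with externally
supplied library sizes, and the relative expression is

    log2[(CPM(circular) + 1) / (CPM(linear) + 1)]

a per-junction, per-sample circular-to-linear log-ratio that is finite by
construction and zero when circular and linear support are equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

LINEAR_RULES = ("max", "mean", "min")


@dataclass
class CountMatrix:
    """Non-negative integer counts (features x samples) plus library sizes.

    ``library_sizes`` are total mapped reads per sample, supplied
    externally; they are the CPM denominator and need not equal the column
    sums of this particular matrix.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValidationError("negative count")
        missing = [
            s for s in self.counts.columns if s not in self.library_sizes.index
        ]
        if missing:
            raise ValidationError(f"no library size for samples {missing}")
        self.library_sizes = self.library_sizes.loc[self.counts.columns].astype(
            float
        )
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")

    @property
    def feature_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns


def circular_count_matrix(junctions, sample_ids, library_sizes) -> CountMatrix:
    """Assemble the circular CountMatrix from called junctions.

    Features are keyed ``chrom:start-end(strand)``; samples without support
    for a junction get 0.
    """
    sample_ids = list(sample_ids)
    rows = {}
    for j in junctions:
        iv = j.interval
        fid = f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"
        rows[fid] = [j.counts.get(s, 0) for s in sample_ids]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=sample_ids, dtype=np.int64
    )
    return CountMatrix(df, pd.Series(library_sizes))


def junction_feature_id(junction) -> str:
    iv = junction.interval
    return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


def resolve_linear_counts(
    junctions, linear_table: pd.DataFrame, library_sizes, rule: str = "max"
) -> CountMatrix:
    """Linear read support per junction: combine the two host boundaries.

    *linear_table* is the long table (chrom, pos, sample_id, count) of
    linearly spliced reads at annotated splice boundaries, 0-based. For a
    circle [start, end) the two boundaries are ``start`` and ``end``; a
    boundary with no entry contributes 0. The default combination is the
    maximum of the two boundary counts (the conservative choice — it yields
    the smallest circular-to-linear ratio); ``mean`` and ``min`` are
    available.
    """
    if rule not in LINEAR_RULES:
        raise ConfigurationError(f"unknown linear-count rule {rule!r}")
    library_sizes = pd.Series(library_sizes)
    sample_ids = list(library_sizes.index)
    lookup = {
        (chrom, pos, sid): cnt
        for chrom, pos, sid, cnt in zip(
            linear_table["chrom"],
            linear_table["pos"],
            linear_table["sample_id"],
            linear_table["count"],
        )
    }
    combine = {"max": max, "min": min, "mean": lambda a, b: (a + b) / 2}[rule]
    rows = {}
    for j in junctions:
        iv = j.interval
        fid = f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"
        row = []
        for s in sample_ids:
            left = lookup.get((iv.chrom, iv.start, s), 0)
            right = lookup.get((iv.chrom, iv.end, s), 0)
            row.append(combine(left, right))
        rows[fid] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return CountMatrix(df, library_sizes)


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: count / library_size * 1e6, columnwise."""
    return matrix.counts.div(matrix.library_sizes, axis=1) * 1e6


def relative_expression(
    circ_cpm: pd.DataFrame, lin_cpm: pd.DataFrame
) -> pd.DataFrame:
    """Entrywise log2((circ_cpm + 1) / (lin_cpm + 1)).

    The two matrices must share features and samples exactly (same order).
    """
    if not circ_cpm.index.equals(lin_cpm.index) or not circ_cpm.columns.equals(
        lin_cpm.columns
    ):
        raise ValidationError(
            "circular and linear matrices are not aligned on features/samples"
        )
    return np.log2((circ_cpm + 1.0) / (lin_cpm + 1.0))
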