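"""Cross-cohort comparison of circRNA sets and grade-wise frequencies.

Different circRNA catalogs use different start conventions (0-based vs
1-based) and sometimes different genome builds, so junction sets are first
unified: 1-based starts are decremented and an optional coordinate-mapping
hook (identity by default, pluggable for liftover) is applied. Unified sets
are matched by exact (chrom, start, end) keys, and grade-specific behavior
is compared through relative frequencies: a junction's occurrence share
within a grade group divided by that group's share of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .pathway import pearson

START_CONVENTIONS = ("zero_based", "one_based")

JunctionKey = tuple[str, int, int]


@dataclass
class CohortOccurrence:
    """Per-junction detection across samples, with grade grouping.

    ``detections`` maps a junction key (chrom, start, end) to the set of
    sample ids where it passed the read-support filter; ``grades`` maps
    sample id -> grade label; ``grouping`` maps grade -> group name (e.g.
    G1/G2 -> 'low', G3 -> 'high').
    """

    detections: dict[JunctionKey, set[str]]
    grades: Mapping[str, str]
    grouping: Mapping[str, str] = field(
        default_factory=lambda: {"G1": "low", "G2": "low", "G3": "high"}
    )

    def __post_init__(self):
        missing_grades = set(self.grades.values()) - set(self.grouping)
        if missing_grades:
            raise ValidationError(
                f"grouping does not cover grades {sorted(missing_grades)}"
            )
        unknown = {
            s for ss in self.detections.values() for s in ss
        } - set(self.grades)
        if unknown:
            raise ValidationError(
                f"detected sample ids missing from sample table: "
                f"{sorted(unknown)[:5]}"
            )

    def sample_groups(self) -> dict[str, str]:
        return {s: self.grouping[g] for s, g in self.grades.items()}


def occurrence_from_junctions(
    junctions, samples: pd.DataFrame, min_reads: int = 1, grouping=None
) -> CohortOccurrence:
    """Build a CohortOccurrence from called junctions and a sample table."""
    detections = {}
    for j in junctions:
        iv = j.interval
        detections[(iv.chrom, iv.start, iv.end)] = {
            s for s, c in j.counts.items() if c >= min_reads
        }
    grades = dict(zip(samples["sample_id"], samples["grade"]))
    kwargs = {} if grouping is None else {"grouping": grouping}
    return CohortOccurrence(detections, grades, **kwargs)


def unify_coordinates(
    junction_keys,
    start_convention: str,
    mapper: Callable[[str, int, int], tuple[str, int, int] | None] | None = None,
) -> tuple[list[JunctionKey], int]:
    """Bring a junction key set onto the canonical 0-based convention.

    ``one_based`` starts are decremented by 1; then *mapper* — a hook with
    signature (chrom, start, end) -> mapped key or None, identity when
    omitted — is applied to every interval. Returns the mapped keys (input
    order preserved) and the count of unmappable (dropped) intervals.
    """
    if start_convention not in START_CONVENTIONS:
        raise ConfigurationError(
            f"unknown start convention {start_convention!r}; "
            f"expected one of {START_CONVENTIONS}"
        )
    shift = 1 if start_convention == "one_based" else 0
    out: list[JunctionKey] = []
    n_dropped = 0
    for chrom, start, end in junction_keys:
        key = (chrom, start - shift, end)
        if key[1] < 0 or key[2] <= key[1]:
            raise ValidationError(f"degenerate interval after unification: {key}")
        if mapper is not None:
            mapped = mapper(*key)
            if mapped is None:
                n_dropped += 1
                continue
            key = mapped
        out.append(key)
    return out, n_dropped


def junction_keys(junctions) -> list[JunctionKey]:
    return [(j.interval.chrom, j.interval.start, j.interval.end) for j in junctions]


def match_junctions(query, reference, tolerance: int = 0) -> dict:
    """Overlap two unified junction key sets.

    At tolerance 0 this is an exact (chrom, start, end) key join; with a
    positive tolerance each coordinate may differ by up to that many bases,
    and each query matches at most one reference (greedy by sorted order).
    Recall percentages are rounded to the nearest integer.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    query = list(query)
    reference = list(reference)
    qset, rset = set(query), set(reference)
    if tolerance == 0:
        n_matched = len(qset & rset)
    else:
        matched_ref: set[JunctionKey] = set()
        by_chrom: dict[str, list[JunctionKey]] = {}
        for key in sorted(rset):
            by_chrom.setdefault(key[0], []).append(key)
        n_matched = 0
        for chrom, qs, qe in sorted(qset):
            for key in by_chrom.get(chrom, []):
                if key in matched_ref:
                    continue
                if abs(key[1] - qs) <= tolerance and abs(key[2] - qe) <= tolerance:
                    matched_ref.add(key)
                    n_matched += 1
                    break
    return {
        "n_query": len(qset),
        "n_reference": len(rset),
        "n_matched": n_matched,
        "recall_vs_query": round(100.0 * n_matched / len(qset)) if qset else 0,
        "recall_vs_reference": round(100.0 * n_matched / len(rset)) if rset else 0,
    }


def relative_frequency(
    occ: CohortOccurrence, min_samples: int = 3, mode: str = "share"
) -> pd.DataFrame:
    """Grade-group relative frequency per junction.

    With the default ``share`` mode,

        freq(c, g) = (n_cg / N_c) / (N_g / N)

    where n_cg is the number of group-g samples containing junction c, N_c
    the total samples containing c, N_g the group size and N the cohort
    size: the junction's occurrence share in the group normalized by the
    group's share of the cohort (1 everywhere for a junction detected
    proportionally). ``count`` mode divides the raw count n_cg by the group
    prevalence N_g/N instead. Junctions detected in fewer than *min_samples*
    samples are excluded.
    """
    if mode not in ("share", "count"):
        raise ConfigurationError(f"unknown frequency mode {mode!r}")
    groups = occ.sample_groups()
    group_names = sorted(set(occ.grouping.values()))
    group_sizes = {
        g: sum(1 for v in groups.values() if v == g) for g in group_names
    }
    if any(v == 0 for v in group_sizes.values()):
        empty = [g for g, v in group_sizes.items() if v == 0]
        raise ValidationError(f"empty grade group(s): {empty}")
    N = len(groups)
    rows = []
    for key in sorted(occ.detections):
        samples = occ.detections[key]
        N_c = len(samples)
        if N_c < min_samples:
            continue
        row = {"chrom": key[0], "start": key[1], "end": key[2], "n_detected": N_c}
        for g in group_names:
            n_cg = sum(1 for s in samples if groups[s] == g)
            prevalence = group_sizes[g] / N
            numerator = (n_cg / N_c) if mode == "share" else n_cg
            row[f"freq_{g}"] = numerator / prevalence
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_detected"]
        + [f"freq_{g}" for g in group_names],
    )


def correlate_cohort_frequencies(
    freq_a: pd.DataFrame,
    freq_b: pd.DataFrame,
    group: str = "high",
    stacked: bool = False,
) -> tuple[float, float, int]:
    """Pearson correlation of grade-group relative frequencies between two
    cohorts over their shared junctions.

    By default only the given group's frequencies (``freq_<group>``) are
    paired; ``stacked=True`` concatenates every shared group column.
    Returns (r, p, n pairs).
    """
    keys = ["chrom", "start", "end"]
    merged = freq_a.merge(freq_b, on=keys, suffixes=("_a", "_b"))
    if stacked:
        cols = [
            c[: -len("_a")]
            for c in merged.columns
            if c.startswith("freq_") and c.endswith("_a")
        ]
    else:
        cols = [f"freq_{group}"]
        if f"freq_{group}_a" not in merged.columns:
            raise ValidationError(f"no frequency column for group {group!r}")
    x = np.concatenate([merged[f"{c}_a"].to_numpy() for c in cols])
    y = np.concatenate([merged[f"{c}_b"].to_numpy() for c in cols])
    if len(merged) < 3:
        raise ValidationError(
            f"only {len(merged)} shared junction(s); need >= 3"
        )
    r, p = pearson(x, y)
    return r, p, len(x)
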