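"""End-to-end orchestration: records -> junctions -> relative expression -> ANOVA.

Thin glue over the per-stage modules, used by the examples, the CLI and
the acceptance script. Either chimeric records (read-level entry) or an
already-assembled circular count matrix (matrix-level entry) can drive it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from . import backsplice, differential, quantify
from .annotation import AnnotationDB
from .backsplice import BackspliceJunction
from .errors import ValidationError
from .intervals import GenomicInterval

_FEATURE_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+.\-])\)$")


def junctions_from_counts(circ_counts: quantify.CountMatrix) -> list[BackspliceJunction]:
    """Rebuild junction objects from a ``chrom:start-end(strand)`` matrix."""
    out = []
    for fid, row in circ_counts.counts.iterrows():
        m = _FEATURE_RE.match(fid)
        if m is None:
            raise ValidationError(f"feature id {fid!r} is not a junction key")
        iv = GenomicInterval(
            m["chrom"], int(m["start"]), int(m["end"]), m["strand"]
        )
        out.append(BackspliceJunction(iv, counts=row[row > 0].to_dict()))
    return out


@dataclass
class PipelineResult:
    junctions: list[BackspliceJunction]
    circ_counts: quantify.CountMatrix
    linear_counts: quantify.CountMatrix
    rel_expr: pd.DataFrame
    anova: pd.DataFrame
    hosts: dict[str, str | None]


def run_pipeline(
    samples: pd.DataFrame,
    linear_table: pd.DataFrame,
    annotation: AnnotationDB,
    chimeric_records=None,
    circ_counts: quantify.CountMatrix | None = None,
    min_reads: int = 4,
    min_samples: int = 1,
    max_span: int = backsplice.DEFAULT_MAX_SPAN,
    linear_rule: str = "max",
) -> PipelineResult:
    """Call, filter, classify, quantify and test junctions for a grade effect."""
    lib = samples.set_index("sample_id")["library_size"]
    if chimeric_records is not None:
        junctions = backsplice.call_backsplices(chimeric_records, max_span=max_span)
    elif circ_counts is not None:
        junctions = junctions_from_counts(circ_counts)
    else:
        raise ValidationError("need chimeric_records or circ_counts")
    junctions = backsplice.filter_junctions(
        junctions, min_reads=min_reads, min_samples=min_samples
    )
    if not junctions:
        raise ValidationError("no junction survives the read-support filter")
    junctions = backsplice.classify_all(junctions, annotation)

    circ = quantify.circular_count_matrix(junctions, samples["sample_id"], lib)
    lin = quantify.resolve_linear_counts(junctions, linear_table, lib, rule=linear_rule)
    rel = quantify.relative_expression(quantify.cpm(circ), quantify.cpm(lin))
    anova = differential.anova_per_feature(rel, samples)
    hosts = {
        quantify.junction_feature_id(j): j.host_gene for j in junctions
    }
    return PipelineResult(
        junctions=junctions,
        circ_counts=circ,
        linear_counts=lin,
        rel_expr=rel,
        anova=anova,
        hosts=hosts,
    )
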