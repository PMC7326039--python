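"""Pathway signature scores and circRNA-pathway correlation structure.

A pathway's per-sample activity is summarized as the geometric mean of its
member genes' expression after adding a pseudo-count — the smallest
strictly positive expression value observed across the set's submatrix
(a raw minimum of zero would collapse the geometric mean). Circles are
assigned to pathways through their host gene; for each in-pathway circle
three Pearson correlations are reported: circle log2(CPM+1) vs the
signature score, circle relative expression vs the score, and circle log
expression vs the host gene's log expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

COMPARISONS = ("circ_vs_pathway", "relexpr_vs_pathway", "circ_vs_host")


@dataclass(frozen=True)
class PathwayGeneSet:
    """A named gene set (GMT record); members unique, order preserved."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicates")


def signature_score(
    gene_expr: pd.DataFrame, gene_set: PathwayGeneSet
) -> pd.Series:
    """Per-sample pathway activity: geometric mean of member expression.

    The pseudo-count is the smallest strictly positive value in the member
    submatrix; every member value gets it added before the geometric mean,
    so zeros are handled without collapsing the score.
    """
    present = [g for g in gene_set.genes if g in gene_expr.index]
    absent = [g for g in gene_set.genes if g not in gene_expr.index]
    if absent:
        warnings.warn(
            f"{len(absent)} member gene(s) of {gene_set.name!r} absent from "
            f"the expression matrix: {absent[:5]}",
            stacklevel=2,
        )
    if not present:
        raise ValidationError(
            f"no member gene of {gene_set.name!r} is in the matrix"
        )
    sub = gene_expr.loc[present].to_numpy(dtype=float)
    if (sub < 0).any():
        raise ValidationError("negative expression value in signature input")
    positive = sub[sub > 0]
    if positive.size == 0:
        raise ValidationError(
            f"all-zero submatrix for {gene_set.name!r}: no positive value "
            "to use as pseudo-count"
        )
    pseudo = positive.min()
    scores = np.exp(np.log(sub + pseudo).mean(axis=0))
    return pd.Series(scores, index=gene_expr.columns, name=gene_set.name)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors differ in length")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pathway_correlations(
    circ_cpm: pd.DataFrame,
    circ_rel_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    sets,
    hosts,
) -> pd.DataFrame:
    """Correlate in-pathway circles with pathway activity and host genes.

    Parameters
    ----------
    circ_cpm : DataFrame
        Circle CPM (features x samples); log2(CPM+1) is taken internally.
    circ_rel_expr : DataFrame
        Circular-to-linear relative expression, same shape.
    gene_expr : DataFrame
        Gene-level expression (CPM, genes x samples).
    sets : iterable of PathwayGeneSet
    hosts : mapping circle_id -> host gene

    A circle enters a pathway's analysis only if its host gene is a member
    of that set; circles on genes outside every set yield no records.
    Returns one row per (circle, pathway, comparison) with Pearson r,
    p-value and n.
    """
    if circ_cpm.shape[1] < 3:
        raise ValidationError("need at least 3 samples for correlations")
    hosts = dict(hosts)
    circ_log = np.log2(circ_cpm + 1.0)
    records = []
    for gene_set in sets:
        score = signature_score(gene_expr, gene_set)
        members = set(gene_set.genes)
        for circle_id in circ_log.index:
            host = hosts.get(circle_id)
            if host is None or host not in members:
                continue
            targets = {
                "circ_vs_pathway": (circ_log.loc[circle_id], score, gene_set.name),
                "relexpr_vs_pathway": (
                    circ_rel_expr.loc[circle_id],
                    score,
                    gene_set.name,
                ),
            }
            if host in gene_expr.index:
                targets["circ_vs_host"] = (
                    circ_log.loc[circle_id],
                    np.log2(gene_expr.loc[host] + 1.0),
                    host,
                )
            for comparison, (x, y, partner) in targets.items():
                try:
                    r, p = pearson(x, y)
                except ValidationError:
                    continue  # constant profile: correlation undefined
                records.append(
                    {
                        "circle_id": circle_id,
                        "pathway": gene_set.name,
                        "partner": partner,
                        "comparison": comparison,
                        "r": r,
                        "p_value": p,
                        "n": len(x),
                    }
                )
    return pd.DataFrame(
        records,
        columns=[
            "circle_id",
            "pathway",
            "partner",
            "comparison",
            "r",
            "p_value",
            "n",
        ],
    )


def count_significant(correlations: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Number of records with p < alpha, broken down by comparison type."""
    out = {}
    for comparison in COMPARISONS:
        sub = correlations[correlations["comparison"] == comparison]
        out[comparison] = int((sub["p_value"] < alpha).sum())
    return pd.Series(out)
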