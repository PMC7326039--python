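"""Grade-wise differential analysis of circular-to-linear relative expression.

Each junction's relative expression profile is tested for a tumor-grade
effect with a one-way fixed-effects ANOVA across the grade groups, raw
p-values are adjusted by Benjamini-Hochberg, and the significant
(discriminative) junctions are clustered hierarchically to expose sample
subgroups. Gene-level differential expression for the set algebra reuses
the same per-feature ANOVA on log2-CPM gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

DEFAULT_ALPHA = 0.05


def anova_per_feature(
    rel_expr: pd.DataFrame,
    samples: pd.DataFrame,
    grouping: str = "grade",
) -> pd.DataFrame:
    """One-way ANOVA per feature across sample groups.

    Parameters
    ----------
    rel_expr : DataFrame
        Features x samples matrix (relative expression, or log2-CPM for the
        gene-level stand-in).
    samples : DataFrame
        Sample table; ``sample_id`` and the *grouping* column are used.
    grouping : str
        Column of *samples* defining the groups (default ``grade``).

    Returns a DataFrame indexed by feature with columns ``F``, ``p_value``,
    ``adjusted_p`` (Benjamini-Hochberg) and one ``mean_<group>`` column per
    group. Features that are constant across all samples get F = 0, p = 1;
    features with zero within-group variance but distinct group means get
    p = 0.
    """
    samples = samples.set_index("sample_id") if "sample_id" in samples else samples
    missing = [s for s in rel_expr.columns if s not in samples.index]
    if missing:
        raise ValidationError(f"samples missing from sample table: {missing}")
    groups = samples.loc[rel_expr.columns, grouping]
    level_names = sorted(groups.unique())
    if len(level_names) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    blocks = []
    for name in level_names:
        cols = groups.index[groups == name]
        if len(cols) < 2:
            raise ValidationError(
                f"group {name!r} has {len(cols)} sample(s); need >= 2"
            )
        blocks.append(rel_expr[cols].to_numpy(dtype=float))

    with np.errstate(divide="ignore", invalid="ignore"):
        F, p = stats.f_oneway(*blocks, axis=1)
    F = np.asarray(F, dtype=float)
    p = np.asarray(p, dtype=float)

    # degenerate rows: scipy yields nan when every observation is identical
    # and inf/0 when the within-group variance vanishes
    group_means = np.column_stack([b.mean(axis=1) for b in blocks])
    all_equal = np.array(
        [np.ptp(row) == 0 for row in rel_expr.to_numpy(dtype=float)]
    )
    nan_rows = np.isnan(F)
    F[nan_rows & all_equal] = 0.0
    p[nan_rows & all_equal] = 1.0
    sep_rows = nan_rows & ~all_equal
    if sep_rows.any():
        # constant within groups but different between them: infinite F
        F[sep_rows] = np.inf
        p[sep_rows] = 0.0
    p[np.isinf(F)] = 0.0

    out = pd.DataFrame({"F": F, "p_value": p}, index=rel_expr.index)
    out["adjusted_p"] = bh_adjust(out["p_value"].to_numpy())
    for name, means in zip(level_names, group_means.T):
        out[f"mean_{name}"] = means
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_sets(
    results: pd.DataFrame,
    hosts,
    genes_de,
    all_circle_hosts=None,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, set]:
    """Set algebra between circle-level and gene-level differential calls.

    Parameters
    ----------
    results : DataFrame
        Output of :func:`anova_per_feature` for the circles.
    hosts : mapping
        feature_id -> host gene id (None for intergenic circles).
    genes_de : iterable
        Gene ids significant in the gene-level analysis.
    all_circle_hosts : iterable, optional
        All host genes with any circle detected; defaults to the values of
        *hosts*.

    Returns the four sets: ``de_circles`` (features at adjusted p < alpha),
    ``de_circle_hosts`` (their unique hosts), ``de_genes_with_circles``
    (gene-level DE genes that host any circle) and
    ``circles_decoupled_from_host`` (DE circles whose host is not DE at the
    gene level).
    """
    genes_de = set(genes_de)
    if all_circle_hosts is None:
        all_circle_hosts = {h for h in dict(hosts).values() if h is not None}
    else:
        all_circle_hosts = set(all_circle_hosts)
    hosts = dict(hosts)
    de_circles = set(results.index[results["adjusted_p"] < alpha])
    de_circle_hosts = {
        hosts.get(c) for c in de_circles if hosts.get(c) is not None
    }
    return {
        "de_circles": de_circles,
        "de_circle_hosts": de_circle_hosts,
        "de_genes_with_circles": genes_de & all_circle_hosts,
        "circles_decoupled_from_host": {
            c for c in de_circles if hosts.get(c) not in genes_de
        },
    }


@dataclass
class ClusterResult:
    """Hierarchical clustering of the discriminative matrix.

    ``sample_linkage``/``feature_linkage`` are scipy linkage matrices;
    ``sample_groups`` maps each sample to 'A' or 'B' (top split, 'A' is the
    group containing the first sample in input order) and
    ``feature_clusters`` maps each feature to 1 or 2 (cluster 1 contains
    the first feature). Leaf orders give the dendrogram ordering for
    heatmap export.
    """

    sample_linkage: np.ndarray
    feature_linkage: np.ndarray
    sample_groups: pd.Series
    feature_clusters: pd.Series
    sample_leaf_order: list
    feature_leaf_order: list


def cluster_matrix(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage Euclidean clustering of rows (features) and columns
    (samples), cut at the top split into two groups each.

    A constant matrix has degenerate (all-zero) distances and is rejected.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 features and >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if np.ptp(values) == 0:
        raise ValidationError("constant matrix: distances are degenerate")

    feat_Z = hierarchy.linkage(pdist(values, metric="euclidean"), method="average")
    samp_Z = hierarchy.linkage(pdist(values.T, metric="euclidean"), method="average")

    feat_cut = hierarchy.fcluster(feat_Z, t=2, criterion="maxclust")
    samp_cut = hierarchy.fcluster(samp_Z, t=2, criterion="maxclust")

    # relabel so the partition containing the lowest-index leaf comes first
    samp_labels = np.where(samp_cut == samp_cut[0], "A", "B")
    feat_labels = np.where(feat_cut == feat_cut[0], 1, 2)

    return ClusterResult(
        sample_linkage=samp_Z,
        feature_linkage=feat_Z,
        sample_groups=pd.Series(samp_labels, index=matrix.columns),
        feature_clusters=pd.Series(feat_labels, index=matrix.index),
        sample_leaf_order=[
            matrix.columns[i] for i in hierarchy.leaves_list(samp_Z)
        ],
        feature_leaf_order=[
            matrix.index[i] for i in hierarchy.leaves_list(feat_Z)
        ],
    )


def group_purity(groups: pd.Series, labels: pd.Series) -> float:
    """Purity of the two-group sample partition against external labels.

    For each group take the fraction of its majority label; return the
    sample-weighted average. Used to score how cleanly the top split
    separates e.g. high-grade samples.
    """
    total = 0
    n = 0
    for _, members in groups.groupby(groups):
        lab = labels.loc[members.index]
        total += lab.value_counts().iloc[0]
        n += len(lab)
    return total / n
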