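"""Grade-wise differential analysis of circular-to-linear expression.

Relative expression log2[(CPM_circ+1)/(CPM_lin+1)] is tested per junction
with a one-way ANOVA across grades G1/G2/G3, BH-adjusted, and the
significant junctions are clustered to expose sample subgroups.
"""

from circgrade import (
    SpikeConfig,
    cluster_matrix,
    generate_annotation,
    generate_cohort,
    run_pipeline,
    significant_sets,
)
from circgrade.differential import group_purity
from circgrade.synthetic import generate_gene_counts

annotation = generate_annotation(seed=1, n_genes=200)
cohort = generate_cohort(
    annotation, n_junctions=800,
    spike=SpikeConfig(n_spiked=80, effect_size=1.2), seed=4,
    with_chimeric=False,
)
result = run_pipeline(
    cohort.samples, cohort.linear_table, annotation,
    circ_counts=cohort.circ_counts, min_reads=4,
)

sig = result.anova[result.anova["adjusted_p"] < 0.05]
truth = cohort.truth.set_index("feature_id")
spiked = set(truth.index[truth["is_spiked"]])
recovered = len(set(sig.index) & spiked)
print(f"junctions tested: {len(result.anova)}")
print(f"significant at adjusted p<0.05: {len(sig)} "
      f"({recovered}/{len(spiked)} truly shifted junctions recovered)")

# set algebra against a gene-level differential analysis
gene_counts, genes_de_true = generate_gene_counts(
    annotation, cohort.samples, seed=5, de_fraction=0.15
)
sets = significant_sets(result.anova, result.hosts, genes_de_true)
print(f"DE circles: {len(sets['de_circles'])} on "
      f"{len(sets['de_circle_hosts'])} host genes; "
      f"{len(sets['circles_decoupled_from_host'])} decoupled from host-gene DE")

clusters = cluster_matrix(result.rel_expr.loc[sig.index])
grades = cohort.samples.set_index("sample_id")["grade"]
print(f"sample split purity vs grade: "
      f"{group_purity(clusters.sample_groups, grades):.2f}")
# A purity well above the 36/58 G3 base rate means the discriminative
# junctions separate a high-grade subgroup, as in the clustered heatmap of
# grade-stratified cohorts.
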