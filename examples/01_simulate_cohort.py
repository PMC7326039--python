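"""Simulate a graded tumor cohort with known circRNA ground truth.

Builds a synthetic annotation and a 58-sample cohort (grades 17/5/36) in
which 40 of 400 back-splice junctions carry a one-log2-unit grade shift of
their circular-to-linear ratio, then prints what the generator produced.
"""

from circgrade import SpikeConfig, generate_annotation, generate_cohort

annotation = generate_annotation(seed=1, n_genes=200)
cohort = generate_cohort(
    annotation,
    n_junctions=400,
    spike=SpikeConfig(n_spiked=40, effect_size=1.0),
    seed=2,
)

grades = cohort.samples["grade"].value_counts()
print(f"samples: {len(cohort.samples)} "
      f"(G1={grades['G1']}, G2={grades['G2']}, G3={grades['G3']})")
print(f"chimeric records emitted: {len(cohort.chimeric):,}")
print("junction context mix:")
print(cohort.truth["context"].value_counts(normalize=True).round(3).to_string())
spiked = cohort.truth.query("is_spiked")
print(f"spiked junctions: {len(spiked)} "
      f"(true G3-vs-G1 shift = "
      f"{(spiked.true_mean_G3 - spiked.true_mean_G1).abs().iloc[0]:.2f} log2 units)")
# The context mix mirrors the ~94% exonic predominance of tumor circRNA
# catalogs; the truth table is the oracle every downstream stage is tested
# against.
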