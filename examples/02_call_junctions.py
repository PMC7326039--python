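"""Call back-splice junctions from chimeric records and annotate them.

A chimeric alignment is back-splice evidence when donor and acceptor sit
on the same chromosome and strand with the acceptor upstream in
transcription orientation. Junctions then pass the >=4-reads-in-one-sample
confidence filter and are classified by genomic context.
"""

from circgrade import (
    SpikeConfig,
    call_backsplices,
    filter_junctions,
    generate_annotation,
    generate_cohort,
    positional_bias,
)
from circgrade.backsplice import classify_all, context_fractions

annotation = generate_annotation(seed=1, n_genes=200)
cohort = generate_cohort(
    annotation, n_junctions=300, spike=SpikeConfig(), seed=3
)

called = call_backsplices(cohort.chimeric)
kept = filter_junctions(called, min_reads=4, min_samples=1)
kept = classify_all(kept, annotation)

print(f"records in: {len(cohort.chimeric):,}")
print(f"junctions called: {len(called)}, after read-support filter: {len(kept)}")
mix = context_fractions(kept)
print("context fractions:", {k: round(v, 3) for k, v in mix.items() if v})

exonic = [j for j in kept if j.context_label == "exonic"]
bias = positional_bias(exonic, annotation)
print("positional bias of exonic circles "
      "(fraction overlapping each mRNA region, classes overlap):")
for region, frac in bias.items():
    print(f"  {region}: {frac:.3f}")
# Most circles connect exons and overlap coding sequence, matching the
# genomic distribution reported for tumor circRNA catalogs.
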