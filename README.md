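# circgrade

Circular RNA (circRNA) analysis for tumor cohorts graded G1/G2/G3, built
around the back-splice junction: a splice event joining a downstream donor
back to an upstream acceptor, producing a covalently closed transcript.
`circgrade` calls such junctions from chimeric alignment records, quantifies
each circle against its linearly spliced counterpart, tests that ratio for
tumor-grade effects, and relates the resulting candidates to miRNA target
sites, pathway activity and external cohorts. It is aimed at bulk RNA-seq
studies of bladder cancer and similar graded cohorts where circRNAs are
evaluated as stratification biomarkers — and it ships a synthetic-cohort
generator with known ground truth so the whole pipeline is testable offline.

## The statistic at the core

For junction *i* in sample *j*, with circular junction count `c_ij`, linear
boundary count `l_ij` and library size `N_j` (CPM(x) = x / N_j × 10⁶):

```
rel_ij = log2[ (CPM(c_ij) + 1) / (CPM(l_ij) + 1) ]
```

the circular-to-linear relative expression. Because both counts come from
the same locus, host-gene expression variation largely cancels in the
ratio; what remains is circularization behavior. Per junction, a one-way
fixed-effects ANOVA across grades tests `rel` for a grade effect, with
Benjamini–Hochberg control across junctions. Downstream:

- **calling/filtering** — head-to-tail orientation test, then ≥ 4
  supporting reads in ≥ 1 sample;
- **context** — exonic / intronic / intergenic per junction side, plus
  CDS/5′UTR/3′UTR positional bias of exonic circles;
- **miRNA sites** — 7/8-bp conserved-family sites fully contained in a
  circle span (sponge candidates);
- **pathway scores** — per-sample geometric mean of member-gene CPM with a
  smallest-positive-value pseudo-count, correlated with circle expression;
- **cross-cohort** — coordinate-convention unification (0- vs 1-based,
  pluggable liftover hook), exact-key overlap, and grade-wise relative
  frequencies `freq(c,g) = (n_cg/N_c)/(N_g/N)` compared between cohorts.

## Worked example

`examples/03_differential_grades.py` simulates a 58-sample cohort
(17 G1 / 5 G2 / 36 G3, six of the G3 muscle-invasive) with 800 junctions,
80 of which carry a 1.2-log2-unit grade shift, and runs the full analysis:

```
junctions tested: 800
significant at adjusted p<0.05: 82 (77/80 truly shifted junctions recovered)
DE circles: 82 on 67 host genes; 72 decoupled from host-gene DE
sample split purity vs grade: 0.91
```

82 junctions pass BH-adjusted significance and 77 of the 80 truly shifted
ones are among them; the significant set's hierarchical clustering splits
the samples into a high-grade-dominated subgroup (purity 0.91 against the
36/58 G3 base rate). "Decoupled" counts DE circles whose host gene is not
itself differentially expressed — circularization moving independently of
transcription. The other examples cover simulation, junction calling,
sponge-site discovery, pathway correlation and cross-cohort comparison,
each printing the numbers it computes and what they mean.

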