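# Methods

## Scope and model

`circgrade` analyzes circular RNA in a graded tumor cohort from four kinds
of evidence: chimeric alignment records (split reads whose two segments map
non-linearly — the raw evidence for back-splicing), linear splice-boundary
counts, a gene annotation, and per-sample grade labels. The unit of
analysis is the back-splice junction, identified by its genomic span
`(chrom, start, end, strand)` in 0-based half-open coordinates.

A chimeric record is accepted as back-splice evidence iff donor and
acceptor share chromosome and strand and the acceptor lies upstream of the
donor in transcription orientation (`donor_pos > acceptor_pos` on `+`,
reversed on `-`). This is the minimal defining property of a head-to-tail
junction; motif checks and realignment heuristics of production callers
are intentionally out of scope. Junction span is capped (default 1 Mb,
configurable), duplicate read ids within a sample count once, and a
junction is retained when at least one sample contributes ≥ 4 supporting
reads (both thresholds configurable).

Relative expression is `log2[(CPM(circ)+1)/(CPM(lin)+1)]` with CPM
denominators taken from externally supplied total library sizes, not
column sums. The linear count of a junction combines its two boundary
counts with `max` by default — the conservative choice, giving the
smallest circular-to-linear ratio; `mean` and `min` are switchable. The
grade test is a one-way fixed-effects ANOVA per junction over all samples
(muscle-invasive samples carry their G3 label; a caller can subset to
non-muscle-invasive before testing), followed by Benjamini–Hochberg
adjustment. BH was fixed as the adjustment method; it is the field default
where a study reports only "adjusted p-values". Features constant across
all samples get F = 0, p = 1; features with zero within-group variance but
separated means get p = 0.

Gene-level differential expression, needed only for the set algebra
(DE circles vs DE host genes vs decoupled circles), reuses the same ANOVA
on log2-CPM gene counts. This is a deliberate stand-in for a moderated
linear model: it keeps the package self-contained and the set algebra
exact, at the cost of less shrinkage at small n.

Clustering of the significant-junction matrix is agglomerative with
average linkage on Euclidean distances, applied to rows and columns, cut
at the top split into two sample groups (A/B) and two feature clusters
(1/2); the group containing the first input sample is "A". The choice of
linkage/metric is documented rather than fitted: with well-separated
grade signatures any standard combination yields the same top split.

miRNA analysis is purely coordinate-level: conserved-family sites are
filtered to lengths 7/8 bp, and a (circle, site) pair requires the site
interval to be fully contained in the circle span. Containment (rather
than 1-bp overlap) encodes the sponge hypothesis — a functional site must
lie on the circle. Strand is ignored by default since site tables are
routinely intersected strand-blind; `stranded=True` switches this. Sites
in introns internal to an exonic circle still count, because the match is
genomic, not transcript-level.

Pathway activity per sample is the geometric mean of member-gene
expression after adding a pseudo-count. The pseudo-count is the smallest
*strictly positive* value in the member submatrix: the natural reading of
"lowest expression value" would be 0 whenever any member is silent in any
sample, collapsing the geometric mean. Scores are correlated (Pearson)
with circle log2(CPM+1), with relative expression, and with host-gene log
expression; no multiple-testing correction is applied inside this module
by default because counts of raw p < 0.05 are the quantity of interest.

Cross-cohort comparison unifies start conventions (1-based starts
decremented), passes intervals through a pluggable coordinate-mapping
hook (identity by default; a liftover implementation can be supplied),
and joins on exact keys. Grade-wise relative frequency normalizes a
junction's occurrence share within a grade group by the group's cohort
share, so a junction detected proportionally everywhere scores 1 in every
group; the alternative raw-count normalization is available behind a
flag. Between-cohort agreement is the Pearson correlation of high-grade
frequencies over shared junctions (optionally stacking groups).

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 58 samples
(G1/G2/G3 = 17/5/36, six G3 samples labelled muscle-invasive), several
hundred to several thousand junctions with a 94/4/2 exonic/intronic/
intergenic context mix, and a configurable subset of junctions whose
circular-to-linear ratio shifts between grades. Everything is a pure
function of (config, seed); cohort files are byte-reproducible.

Counts are negative binomial with marginal dispersion 0.3 — a typical
between-patient overdispersion for human cohorts. Crucially, the circular
and linear counts of one junction in one sample share a latent
host-expression factor (gamma, mean 1): back-spliced and linearly spliced
reads are transcribed from the same locus, so their biological variation
is common. Conditional on the factor, counts are NB with a small residual
dispersion (default 0.05, covering technical noise plus
circularization-rate variability), and the factor variance is set so each
count's marginal dispersion equals the configured 0.3. This joint
structure is what makes the ratio statistic informative — the shared
factor cancels — and a generator with fully independent circular and
linear draws would contradict the premise of ratio-based analysis by
putting a noise floor of >1 log2 unit on it.

Grade effects are injected on the scale the statistic measures: for a
spiked junction the circular mean in the affected grades (default G3) is
rescaled on the (CPM+1) axis so the true relative-expression difference
equals `effect_size` log2 units exactly, with per-junction direction
(up/down/random). Linear counts never carry grade effects, so the
differential truth is unambiguous. Junction baseline abundances are
lognormal (median 10 counts at the reference depth, σ = 0.7 on the log
scale), chosen to resemble a detected-circRNA catalog: mostly
low-to-moderate support with a long upper tail. Simulated depth defaults
to 10⁶ reads/sample (the upper end of the desk-scale band) because
counting noise per CPM unit grows as depth shrinks; at this depth the
ANOVA operating characteristics are dominated by the biological model
rather than by Poisson noise, while the full pipeline still runs in
seconds. Junction contexts are drawn up front and coordinates
rejection-sampled within each context so key collisions cannot skew the
context mix.

What the generator does **not** model: sequence content (no FASTQ-level
simulation), GC or length biases, correlated junctions within one host
gene, batch effects, and aligner artifacts beyond simple non-qualifying
noise records. Passing tests therefore demonstrate correctness of the
statistical machinery and coordinate logic under a faithful count model —
not robustness to alignment pathologies of real data.

`layout_seed` separates the cohort's "biology" (junction coordinates,
baselines, spike assignment) from sampling noise, so two cohorts can be
drawn from the same grade-effect truth for cross-cohort experiments.

## Numerical choices and degenerate inputs

- Coordinates are validated at construction (`end > start`, `start ≥ 0`);
  1-based dialects are shifted exactly once, at the reader.
- Chromosome names match as exact strings; an optional reader flag strips
  a `chr` prefix, never silently.
- ANOVA requires ≥ 2 groups with ≥ 2 samples each and names the offending
  group otherwise; BH inputs must lie in [0, 1].
- Pearson correlation requires n ≥ 3 and non-zero variance in both
  vectors; in-pathway circles with constant profiles are skipped rather
  than reported with undefined r.
- Clustering rejects constant matrices (degenerate distances). Ties in
  recurrence rankings break alphabetically; cluster labels attach to the
  partition containing the lowest-index element, making outputs
  order-stable.
- The 10,000-junction calibration cohort uses a 2,000-gene annotation so
  the exonic junction key space comfortably exceeds the junction count.

## Known limitations

- With the default cohort (17/5/36), dispersion 0.3 and the lognormal
  abundance profile, BH-adjusted recovery of 1-log2-unit spikes averages
  just under 80% (the acceptance suite computes ≈ 0.78): junctions in the
  low-abundance tail remain power-limited by counting noise. Recovery of
  effects ≥ 1.2 log2 units is near-complete (see
  `examples/03_differential_grades.py`).
- The gene-level DE stand-in shares none of limma/voom's variance
  shrinkage; its calls at n = 5 (G2) are noisier than a moderated model's.
- Exact-key junction matching treats ±1-bp boundary wobble as a mismatch
  unless a tolerance is passed.
- The liftover hook ships identity only; genome-build mapping requires a
  user-supplied mapper.
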