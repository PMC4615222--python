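# Methods

## Synthetic experiment model

The generator emulates a knockdown-vs-control miRNA profiling experiment in
a larval tissue. Its output is the joint set (mature count matrix, precursor
count matrix, per-sample FASTQ, qPCR Ct table, ground-truth table) for a
design of 3 genotypes (two parental controls, one knockdown) × 2 biological
replicates.

**Baseline abundance.** Each of the `n_features` (default 109) miRNAs draws
a relative mean from a two-component log-normal mixture: mode means 1 and
100 (only their 100-fold ratio matters; per-million normalization removes
the scale), mixture weights 0.8/0.2 (low/high), and a within-mode natural-log
sigma of 0.6. The weights encode the typical skew of tissue miRNA profiles —
a minority of miRNAs carries most of the reads — while keeping the kernel
density of log10 expression clearly bimodal with peaks ~2 decades apart; the
resulting overall dynamic range across 109 features is 10³–10⁴-fold.

**Counts.** Per sample, sequencing depth is uniform on 12–22 million reads
and the expected mature-miRNA yield is depth × `mirna_fraction`
(default 0.0112). Feature means are the yield allocated proportionally to
baseline relative means, multiplied in knockdown samples by the spiked fold
change; the allocation weights are the *baseline* composition, so spiking
does not renormalize control samples. Counts are negative binomial
(Gamma–Poisson), `var = μ + α·μ²` with dispersion `α` defaulting to 0.05
(replicate CV ≈ 22% at high counts, a typical bulk-replicate level; no
replicate-variance estimate exists to emulate, so this is the package's
choice). Analyses whose stated premise is that replicate ratios stay within
the 2-fold concordance window (the spiked-recovery run and the
sensitivity/specificity property) use `α = 0.01`, where counting noise
dominates.

**Effects.** `study_effects()` builds the study-outcome-like spike: 11
up-effects at +3 to +49.5-fold and 6 down-effects at −3 to −4-fold, placed
(deterministically per seed) on features from the upper half of the
low-abundance mode — changed miRNAs are poorly expressed, but must carry
enough reads that counting noise does not swamp replicate comparisons, as a
validated hit would. One up-effect is labeled post-transcriptional
degradation and one down-effect a processing defect; the rest are
transcriptional/indirect. Precursor count means follow the spiked fold
change only for transcriptional effects; degradation and processing effects
leave the precursor at baseline — this is the signal the mechanism
classifier must recover.

**Reads.** Each mature read is `mature_seq + adapter` truncated to the read
length (default 50 nt; the Illumina TruSeq small RNA 3' adapter is the
default). Contaminant reads are 18–22 nt fragments of the 30 nt Drosophila
2S rRNA sequence plus adapter — they survive trimming and size selection but
match no reference feature. Their number per sample is
`round(assigned × (1−f)/f)`, so the realized miRNA-mapped fraction equals
`mirna_fraction` up to integer rounding while the total read count equals
the nominal library size only in expectation (the count matrix itself is
random). Mature read counts equal the count matrix exactly; read order is
shuffled; FASTQ quality is constant maximal, since no downstream stage uses
it. No sequencing-error or non-templated-addition model is included.

**Ct tables.** The qPCR simulator inverts the ΔΔCt model:
`Ct = baseline_ct − log2(relative expression) + N(0, noise_sd)` per well,
with the normalizer held at fold change 1 and 4 technical wells (2 cDNA × 2
qPCR) per biological replicate (default 4 biological replicates, noise sd
0.1 cycles). There is no separate biological-variance term; well noise is
the only stochastic component.

**Randomness.** All stochastic stages derive independent PCG64 streams from
the single config seed via `SeedSequence.spawn`, so any stage can be
re-generated in isolation and stage reordering cannot perturb results.

## Quantification

Exact matching replaces alignment: with 18–22 nt reads and a
mature-sequence reference, a read either equals a mature sequence
(T/U- and case-insensitive) or it does not; mismatch tolerance is out of
scope. Multi-mapping reads (identical mature sequences under different ids)
contribute 1/k to each of k features and the matrix stays real-valued to
avoid order-dependent assignment. Trimming cuts at the leftmost full
adapter occurrence, falling back to the longest adapter prefix (≥5 nt) at
the 3' end; reads without adapter evidence pass through unchanged and are
left to the 18–22 nt size selection. "RPM" carries no length term: mature
miRNAs are near-constant length. Both per-million denominators are
available — assigned (miRNA-mapped, default) and total size-selected
reads — because either convention is defensible; nothing downstream depends
on the choice beyond a common scale factor per sample. Detection requires
strictly more than `min_reads` (default 1, i.e. ≥2 reads) in *every* sample.

## Filter cascade

Concordance filters are strict ("differs more than 2-fold" excludes at
ratio > 2); candidate and category thresholds are inclusive (≥). Parental
concordance compares genotype *means*; per-replicate disagreement is the
replicate filter's job. The grouped control is the unweighted mean of all
four parental replicate expressions (library size is already handled by
normalization). The pseudocount defaults to 0 with an explicit error on
0/0 — the detected universe has ≥2 reads everywhere, so zeros signal an
upstream problem; a small pseudocount can be configured for permissive
runs. A single-sided zero yields ±inf, which categorizes as a ≥2-fold
change. The whitelist is an explicit, logged override for features that
fail concordance but are retained anyway; it defaults to empty and is
surfaced in results as a `whitelisted` flag.

## Mechanism classification

Significance means a two-sided two-sample t-test at `alpha = 0.05` on
replicate-level values (knockdown replicates vs all four control
replicates when the pipeline builds evidence itself). "Precursor unchanged"
is encoded as non-significance — no precursor fold-change threshold is
imposed. The decision table is total; the one combination without a clean
mechanistic reading (mature and precursor significant with opposite signs)
is called transcriptional/indirect and flagged discordant. The packaged
evidence fixture (`data/mechanism_evidence_synthetic.tsv`) carries the
seven qPCR-validated hits of the emulated study with published mature fold
changes; precursor magnitudes were never tabulated, so the fixture's
precursor values are synthetic nominal numbers encoding only direction and
significance. With pipeline-internal evidence the t-test runs on n = 2 vs
4 replicates; its power is limited, which is faithful to the design rather
than a defect of the classifier.

## Density profiles

Gaussian kernel, Silverman bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)` by
default, evaluated on a 512-point grid spanning the data ± 3 bandwidths.
The KDE is computed as an explicit mean of scaled normal pdfs so that
all-equal input degrades gracefully to a single narrow peak instead of a
singular-covariance failure; the test suite cross-checks the curve against
`scipy.stats.gaussian_kde` at matched bandwidth. Peaks are local maxima at
or above 10% of the global maximum (configurable); peak location precision
is bounded by the grid step. Fold changes are plotted on a symmetric axis
`sign(f)·log2|f|`, with reference lines at ±1 (2-fold). No formal
bimodality test is attempted.

## ΔΔCt analysis

Technical wells are averaged within each biological replicate before ΔCt is
formed; the t-test runs on per-replicate ΔCt, the scale on which noise is
approximately additive, not on fold changes. Amplification efficiency is
fixed at 2. Adding a constant to all Ct values of one sample cancels in
ΔCt — the normalizer absorbs loading differences — and this invariance is
tested. When both groups are noise-free the t statistic degenerates; the
p-value is then defined as 1 for a zero ΔΔCt and 0 otherwise.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline recovers *constructed* truth
under the stated noise model: NB counts with independent features, exact
reads, a single contaminant class, and well-behaved qPCR noise. Real small
RNA-seq additionally has sequencing errors, isomiRs and non-templated 3'
additions, correlated features (clustered miRNAs sharing a transcriptional
unit), mapping ambiguity beyond exact duplicates, and parental genotypes
that differ genuinely rather than only by noise. None of these are modeled,
so test results bound implementation correctness, not real-data
performance. Problem sizes in the test and acceptance runs are chosen at
desk scale: 109-feature count simulations at full 12–22 M library depth
(counts only), and read-level round trips at 100,000 reads/sample.

## Known limitations

- Exact matching undercounts features whose reads acquire errors or
  modifications; this is by construction, not a bug to fix.
- The parental-discordance rate in null simulations (~0–5%) is lower than a
  real two-genotype comparison would show, because genotype differences are
  not modeled — the printed 92.7% concordance figure is reproduced from a
  constructed table, not from the generator.
- `classify_table` accepts sequencing-scale or qPCR-scale evidence alike; it
  does not enforce that evidence came from validation-grade measurements.
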