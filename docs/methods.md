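# Methods

This note documents the models and procedures `adenoclone` implements,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## The position-local noise model

Ultra-deep amplicon sequencing (depth 10³–10⁵) of ~250 bp targets can
resolve variants far below 1% VAF, but only against a noise model,
because substitution error rates vary by position and context over
roughly 0.01–0.3% VAF — the same order as the signals of interest.

For lesion profile *a* and matched control profile *n* over the same
amplicon, the per-position statistic is

    d_i = max over y in Σ of | a_{y,i} − n_{y,i} |,   Σ = {A, C, G, T}.

The maximum runs over all four alleles, the reference included; because
the reference difference mirrors the summed variant differences, d is
essentially "the largest allele-fraction perturbation at this position".
The *called* allele, by contrast, is always the best non-reference
allele — a somatic call must name a variant.  Strand is recorded in the
count tables but pooled before VAF computation; strand information is
consumed only by the exome filter's both-strands rule.

For a tested position *j* with window half-width K, the background is
the empirical mean μ_j and SD σ_j of {d_k : k = j−K,…,j−1, j+1,…,j+K},
truncated at region boundaries (no padding — padding invents data),
restricted to positions where both samples have depth, and always
excluding *j* itself so a true variant cannot contaminate its own null.
Assuming X ~ N(μ_j, σ_j²), position *j* is called somatic when all
three of the following hold:

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | one-sided tail level for P(X > d_j) |
| `d_min` | 0.001 | minimum VAF difference (guards significant-but-negligible calls) |
| `control_vaf_max` | 0.01 | ceiling on every non-reference control allele at *j* |
| `K` | region length | window half-width; the default makes the window the whole amplicon minus *j* |
| `sd_ddof` | 0 | population SD for σ_j (sample SD available) |

Numerical choices: allele ties in the argmax break alphabetically; a
degenerate window (fewer than two defined values) is an error carrying
the position; σ_j = 0 collapses the null to a point mass (p = 0 when
d_j > μ_j, else 1).  No multiple-testing correction is applied by
default, matching validation-style use on designated candidate
positions; a Bonferroni option over the tested positions exists for
scan-style use.

**Calibration.** The d statistic is non-negative and right-skewed, so a
normal 5% upper-tail rule is not exactly a 5% test.  On a genuinely
Gaussian difference track the machinery is calibrated (empirical
type-I ≈ 0.05; this is a property test).  Under the package's
beta-heterogeneous error generator the p_pass flag fires at ≈ 0.07 on
null data — an intrinsic property of applying a normal tail rule to a
skewed statistic, observed at nearly the same rate under homogeneous
and heterogeneous error variants alike.  Scan-style users should treat
α as nominal and rely on the d_min/control gates, correction, or
candidate restriction.

## Exome candidate filters

A candidate SNV is discarded when *any* of: total reads < 100, mutant
reads < 7, disease VAF < 0.024, germline VAF > 0.01, mutant support on
one strand only, or presence in a population database.  Every threshold
is configurable; the mutant-read default follows the formal statement
of the criteria (discard when < 7).  Population-database membership is
a precomputed boolean in the input table, not a live lookup, keeping
the package download-free and the database version explicit.

## Negative-panel hotspot cutoffs

Where no germline sample exists (macro-dissected endometrium and
myometrium), a hotspot alteration counts as a true mutation when its
VAF strictly exceeds mean + 3 SD of the VAFs at that hotspot across a
negative panel of normal-endometrium samples.  Percent is the canonical
unit in this module — cutoffs are reported in percent, and unit
conversion happens only at module boundaries, avoiding silent 100×
errors.  SD uses ddof 0 by default (configurable; the convention behind
the published panel SDs is not stated).  A hotspot class pooling
several codons takes the maximum single alt-allele VAF as the class
VAF — conservative for detection.  The full panel is used by default;
leave-one-out cutoffs are available.

## Multi-region clonality

Per-sample calls over shared targets assemble into a mutations ×
samples VAF matrix.  A cell is *present* when its call has a true
verdict **and** lesion VAF ≥ 1% (configurable).  The VAF floor matters:
the noise test at α = 0.05 leaves a few-percent per-cell false-positive
rate that would otherwise convert private mutations into spuriously
"restricted" ones; the floor mirrors how VAF heatmaps are displayed and
suppresses sub-percent noise exceedances without touching real lesion
VAFs (≥ ~2% in this tissue context).

Sharing classes are count-based and mutually exclusive — *ubiquitous*
(present in every assayed sample of the dominant lesion tissue class,
requiring at least two), *restricted* (> 1 lesion sample but not all),
*private* (exactly one) — with two orthogonal flags: cross-lesion
sharing (adenomyosis ∩ endometriosis) and normal-endometrium sharing.
Blood columns are germline reference: displayed, never counted.
"Ubiquitous" requires all *assayed* samples, not all samples, because
multi-region panels assay targets unevenly.

## Bisulfite methylation

Per CpG, frequency = methylated / (methylated + unmethylated); reads
with any other base at the CpG are excluded from the denominator so
sequencing error inflates neither state.  The per-sample amplicon
summary is the unweighted mean over CpGs (matching per-region
reporting granularity); a depth-weighted mean is available.  Conversion
efficiency is estimated at non-CpG cytosines, with a warning below
0.98.  Group comparisons use Welch's t-test on per-sample amplicon
means.  The mutant-group size in the reference bisulfite design is 11
(the plotted cohort; a surrounding text mention of 13 is inconsistent
with it and not used).

## Cohort statistics

Fisher's exact test is two-sided by the point-probability method (sum
of all fixed-margin tables whose probability does not exceed the
observed table's); the reported odds ratio is the sample cross-product
estimate, NaN/inf-flagged when undefined.  Welch's t-test uses
Satterthwaite degrees of freedom.  qPCR relative expression is
2^−ΔΔCt against a housekeeping reference and the mean ΔCt of the
control condition.  The Table-1-style battery runs one Fisher test per
boolean characteristic with no multiple-testing correction (matching
the source analysis convention).

## Synthetic-data generators

The generators produce every input the pipeline consumes, with the
statistical structure the analysis assumes; they are pure functions of
(parameters, seed) and emit ground truth sufficient to score every
downstream inference.

**Error model.** Per-sample, per-position, per-substitution error rates
draw from a beta distribution with mean 6.5×10⁻⁴ and SD 9×10⁻⁴ (capped
at 10⁻²), matched to the negative-panel noise scale observed in normal
endometrium (hotspot VAF mean 0.065%, SD 0.09%).  Rates are drawn
independently per sample rather than locked per position across
samples: the windowed background model pools positions as
exchangeable, and the negative-panel generator treats the beta as the
across-sample law at a hotspot, so per-sample draws make the two
generators one consistent model.  Null difference tracks then have
magnitudes of roughly 0.03–0.3%, the scale the method is designed for.

**What is not emulated.** Real amplicon error is partly
position-locked (shared chemistry between samples at the same site),
context-dependent (e.g. elevated C>T), and correlated along reads; PCR
duplicates, UMIs, strand bias and FFPE deamination artifacts are not
modeled, and reads are never represented individually (counts only).
Passing tests therefore demonstrate the pipeline's statistical
behaviour under its own assumptions, not performance on any particular
instrument's error spectrum.

**Clones.** Somatic variants are heterozygous diploid: a clone at cell
fraction f contributes VAF = purity × f / 2.  The purity knob emulates
the bulk-versus-microdissected contrast (epithelial enrichment raises
observed VAFs).  The reference multi-region design — six adenomyosis
regions, one endometriosis lesion, normal endometrium, normal
myometrium, one blood control, two 250 bp amplicons at depth 10⁴ —
carries five clones spanning the sharing spectrum (trunk 8%, restricted
5%, private 2.5%, cross-lesion 4%, normal-shared 3%; all lesion VAFs at
or above the smallest VAF reported in the motivating cohort, 2.47%).

**Bisulfite.** Methylated cytosines always read C; unmethylated ones
read T with the conversion probability, so incomplete conversion
inflates apparent methylation by (1−p)(1−conversion).  The two-group
cohort generator defaults to 20 vs 11 samples at mean methylation 0.05
vs 0.5 with per-sample beta variation (concentration 30, giving
realistic inter-sample spread of a few percentage points at low
methylation).

**Cohort metadata.** Patient tables draw mutation status at the
observed cohort prevalence (26/70) and boolean characteristics at
status-conditional prevalences mirroring the published
characteristic-by-status table; generating odds ratios are returned
alongside.

## Problem sizes and determinism

The acceptance measurements use 10,000 null positions (40 regions × 250
positions, depth 10⁴) for calibration, 500 regions for power at VAF
2.47%, 100 simulated patients (500 mutation instances) for clonality
recovery, exhaustive enumeration of all 2×2 tables with total ≤ 40 for
the Fisher oracle, 2,000 threshold-straddling candidates for the filter
oracle, and 1,000 simulated cohorts for methylation power — sizes at
which the Monte-Carlo error of each measured rate is well below its
acceptance margin while the whole suite runs in a couple of minutes.
Every stochastic computation takes an explicit seed; identical seeds
reproduce identical outputs bit-for-bit.

## Known limitations

Indels, multi-sample joint calling, overlapping-amplicon
reconciliation, subclonal deconvolution/CCF estimation and phylogeny
reconstruction are out of scope.  The noise test's nominal α is
anti-conservative on skewed nulls (see Calibration above).  The
per-cell presence rule in clonality matrices (verdict + VAF floor) is
one reasonable reconstruction of a display convention whose exact
thresholds are not published.
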