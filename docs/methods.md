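# Methods

This note records the statistical model behind each QC stage, the
parameter defaults and why they were chosen, what the synthetic cohorts
do and do not emulate, and the numerical conventions a maintainer needs.

## Data model and PLINK codecs

Genotypes are alt-allele (a2) dosages in an int8 sample × variant matrix
with −1 for missing. The binary codec follows the published 2-bit table
(00 = hom a1, 01 = missing, 10 = het, 11 = hom a2, variant-major, zero
pad bits) and is verified against an independent byte-level packer and
exhaustively over all 256 payload bytes. Sample-major files are rejected
outright: silently transposing a rare layout is a worse failure mode than
an explicit error. Chromosome codes 23–26 are normalised to X/Y/XY/MT at
read time.

The text dialect carries no allele-order metadata, so `.ped` alleles are
collected in order of first appearance and reconciled at the end to
a1 = minor / a2 = major (ties keep first appearance). Consequence: a
variant monomorphic in the text file gets a `0` placeholder for the
unobserved allele — the dosage matrix still matches the binary
representation, only the label is unknowable.

## Call rates

The denominator of the sample call rate is the fileset's full variant
list, including variants called in no sample; this matches the standard
missing-rate definition and is reproducible without a preliminary
filtering pass. Threshold comparisons are inclusive (a rate exactly at
the threshold passes). The default flag thresholds are 0.98 for samples
and 0.95 for variants, the values conventionally recommended for array
QC; the summary ladder (0.90/0.95/0.98/0.99) is reporting, not
filtering. Y-chromosome variant call rates are computed over reported
males only — females are uncalled on Y by biology, and sex-chromosome
quality must be judged within a homogeneous sex subpopulation.

## MAF

Allele counts treat every non-missing call as diploid, so the default
MAF table covers autosomes + PAR only; mixing hemizygous male X/Y calls
into a diploid denominator would bias frequencies, and sex-chromosome
MAF is available explicitly via masks instead. Monomorphic variants
report maf 0 with the absent allele as minor and are kept, not dropped.
Reference concordance intersects on variant id and reports Pearson r,
undefined below 3 shared variants. No MAF removal filter is applied by
default; filtering is the caller's decision.

## Sex check

The estimator is the method-of-moments excess homozygosity
F = (O − E)/(N − E) with the small-sample correction n/(n−1) on the
expected term — the de-facto statistic the published decision ranges
(males 0.98–1, females −0.3–0.2) were calibrated on. Allele frequencies
are taken from all samples' calls treated as diploid in a single
deterministic pass; a two-pass mode re-estimates from inferred females.
Variants monomorphic in the frequency pool or resting on fewer than two
alleles are excluded from both O and E. A sample whose every informative
call is homozygous gives F = 1 exactly (the ratio degenerates to
(N−E)/(N−E)), which is why simulated hemizygous males sit at the male
bound with no sampling noise. Estimates in the gap zone (0.2, 0.98) or
below −0.3 are flagged out-of-range; reported sex is never rewritten.
Heterozygous male X calls are left in place — depressed F *is* the
signal. Y calls never enter the inference.

PAR coordinates ship for GRCh37 and GRCh38 (default GRCh37). PAR1/PAR2
use the canonical coordinates; the debated third region is included by
default as the approximate Xq21.3/Yp11.2 homology block and can be
toggled off (`include_par3=False`). Variants on chromosome "XY" are PAR
by definition.

## Hardy–Weinberg exact test

The two-sided exact conditional test: given N genotypes and n_rare minor
alleles, heterozygote counts of matching parity are enumerated, their
conditional probabilities computed in log-space via log-gamma (stable to
allele counts in the thousands), normalised by log-sum-exp, and summed
over outcomes no more likely than the observed one. A relative tie
tolerance of 1e−12 keeps exactly-tied outcomes included despite
floating-point rounding; the suite checks exact agreement with a
rational-arithmetic enumeration oracle for minor-allele counts ≤ 40 and
that outcome probabilities sum to 1. Monomorphic input returns p = 1. A
mid-p variant (half the observed outcome's probability) is available
behind a flag, default off — the plain exact test is the conservative
field default.

The scan stratifies by reported race (unknown-race samples excluded by
default, includable as their own stratum), optionally restricts to
controls, and tests autosome + PAR variants. X-specific testing would
use females only. The Bonferroni multiplier is the per-stratum count of
variants actually tested (recorded in the output), not the array's full
variant count: the stated adjustment names no multiplier, and the
per-test-family reading is the defensible one. Flagged variants
(adjusted p < 0.05) are reported, never removed.

## Heterozygosity ratio

n_het / n_nonref_hom over diploid calls. The fileset does not define a
"reference" allele, so orientation is an explicit parameter: a1 is
reference by default (dosage 2 = non-reference homozygote), invertible
globally or per variant via a reference-allele table; the ratio is
documentedly *not* invariant under allele relabelling. A sample with no
non-reference homozygotes is "undefined", never an exception. Because
the ratio's typical value is ancestry-dependent, outlier flags are
relative to the sample's race-stratum median (high > 1.5×, low < 0.5×;
unknown-race samples use the overall median). The multipliers are this
package's choice — no published absolute bounds exist — and are wide
enough that pooled-DNA contamination (which roughly an-order-of-magnitude
inflates the ratio) separates cleanly from cohort scatter. Strata below
3 samples are kept in tables but dropped from plots.

## Ancestry PCA

Standardization is the population-genetics convention
(g − 2p)/√(2p(1−p)) with missing entries mean-imputed (hence exactly 0
after centering). Absent a user AIM list, ancestry-informative markers
are approximated by autosomal variants with MAF ≥ 0.05 and call rate
≥ 0.95, thinned by greedy sliding-window LD pruning (window 50, step 5,
r² > 0.2 drops the later variant). Scores come from an exact SVD with a
fixed sign convention (largest-magnitude loading positive). The race
check fits one centroid (componentwise median) and robust scale
(1.4826·MAD) per reported race with ≥ 3 samples on the first two
components; a sample farther than 3 robust-z units from every centroid
is a hybrid/outlier, otherwise a nearest centroid differing from the
reported label is a mismatch. The rule replaces visual inspection of the
PC1–PC2 plot and its z cut-off is configurable; at z_max = 3 roughly a
percent of a homogeneous cluster's tail can flag, so the cut-off should
be raised for tight single-ancestry cohorts.

## Duplicate concordance

Match = equal dosage after allele reconciliation: records with swapped
a1/a2 are compared as d vs 2−d. Allele sets that disagree even after a
swap (e.g. a probable strand flip) are incomparable and excluded — strand
correction is deliberately out of scope. Sample pairs come from the
metadata `dup_group` column (all within-group pairs); variant pairs from
shared (chrom, bp) or a user list. The 0.99 flag threshold is a
configurable convention, not a published constant. With no duplicates
designated the stage reports "not assessed" rather than an empty pass.

## Synthetic cohorts

The generator draws what each stage assumes: autosomal genotypes from
(p² + fpq, 2pq(1−f), q² + fpq) with per-variant inbreeding f; female X
diploid HWE; male X hemizygous coded as the matching homozygote; PAR
diploid in both sexes; Y missing in females; missingness
1 − (1−r_sample)(1−r_variant) per call; duplicates as copies with
independent per-genotype error (an error becomes one of the other two
genotypes uniformly, so the error rate equals the expected discordance);
populations as per-block allele-frequency vectors (default ± drift
around shared base frequencies). Contamination is modelled as pooled
DNA: the mixing-weighted dosage average re-called to a genotype with the
middle band [0.5, 1.5] called heterozygous — the mechanism by which
mixed DNA inflates array heterozygosity — applied to diploid columns
(hemizygous-X pooling would need a sex-aware caller and is out of
scope). A per-variant random *pick* between two parents was considered
and rejected: it averages the parents' heterozygosity instead of
exceeding it, so it cannot reproduce the contamination signature the
heterozygosity-ratio check looks for.

One root seed feeds a named substream per generation stage, so equal
specs give byte-identical filesets and adding a stage never perturbs
earlier stages' draws. What the cohorts do **not** emulate: linkage
disequilibrium (variants are independent except by construction),
genotype-calling intensity artefacts, batch effects, and relatedness —
so passing tests demonstrate the estimators and decision rules, not
robustness to every real-data pathology.

## Problem sizes and determinism

Test and acceptance simulations run at desk scale chosen for tight
Monte-Carlo error at interactive runtimes: sex-check calibration at
200 samples × 2,000 X variants (female F has SD ≈ 0.03 there, so the
0.2 ceiling sits > 4 SDs out), the heterozygosity-ratio expectation at
100 × 20,000, the planted-defect cohort at 300 × ~4,000. The pipeline is
end-to-end deterministic given input, config, and seed: identical TSVs
and byte-identical HTML (figures are PNG-embedded with fixed metadata).
QC findings never set a nonzero exit code; only operational errors do.
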