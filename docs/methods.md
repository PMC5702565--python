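# Methods

This note documents the models, procedures and numerical choices behind
`rareburden`, and what the synthetic-data tests do and do not establish
about real cohorts.

## Cohort representation

Genotypes are unphased diploid alt-allele dosages {0, 1, 2} with −1 as
the missing-call sentinel; ploidy is fixed at 2. All allele-count
arithmetic runs on this matrix. Coordinates and alleles follow VCF
conventions (1-based positions, anchored-base indels); cohorts
round-trip losslessly through plain-text VCF 4.2 (GT only, gene symbol
in INFO) plus a two-column phenotype sheet.

## Per-locus frequencies

The case (control) alt-allele frequency at a locus is the summed dosage
over called genotypes divided by 2 × the number of called samples in
that group. Missing calls are excluded from numerator and denominator;
no imputation. A group with zero called samples at a locus is an error,
not a zero.

## The burden test

**Statistic.** Loci are the pairs; the paired difference at locus *l* is
d_l = case_freq_l − control_freq_l. Absolute differences are midranked
(`scipy.stats.rankdata`) and W⁺ sums the ranks of positive differences.
Zero differences are dropped before ranking by default; the Pratt
variant ranks them and then excludes them from W⁺. Both are exposed
because published descriptions of this test family rarely state which
convention was used. Paired differences are rounded at 12 decimals
before ranking so that ties between decimal frequencies survive binary
floating-point subtraction; 10⁻¹² is far below any meaningful frequency
difference.

**Null.** Under the hypothesis of no systematic case/control difference
the signs of the d_l are exchangeable, so the null distribution of W⁺
is generated by independent random sign flips. Since |d_l| is invariant
under flips, the ranks are fixed and each permutation reduces to a
random subset-sum of the ranks — the permutation loop is a single
Boolean matrix product. The empirical p-value is (r+1)/(B+1) with r the
number of permuted statistics as or more extreme, so it is never zero;
two-sided p doubles the smaller tail, capped at 1. For m ≤ 20 nonzero
differences an exact oracle enumerates all 2^m sign patterns; the
Monte-Carlo p converges to it within binomial error, which the tests
check at 3 SE for every sidedness × zero-policy variant.

**Sidedness.** The default alternative is one-sided `greater` (damaging
alleles over-represented in cases, the direction of the hypothesis the
candidate genes were selected under). On the published 14-locus table,
W⁺ = 79 over 13 nonzero differences (dropping zeros) and the exact
sign-flip p-values are: one-sided 0.0081 (zeros dropped) / 0.0092
(Pratt), two-sided 0.0161 / 0.0183. The published empirical value of
0.0416 from 10K permutations is not exactly recoverable from the
printed frequencies under any of these variants; the two-sided Pratt
variant comes closest and is the one the reproduction report highlights
alongside all four.

**Ancillary summaries.** Detection power for a variant of frequency f on
n sequenced chromosomes is 1 − (1 − f)^n. The published narrative pairs
a "152 chromosomes" phrasing with 78%; the formula gives 53% at n = 152
and 78% at n = 304, so the reproduction layer evaluates n = 304 and
annotates the reconciliation. Carrier tallies report heterozygote and
homozygote counts per group with homozygote percentages over group
size; case-only scans keep loci with alt alleles in cases and none in
controls (counts when available, else frequencies); di-genic carriers
are samples with nonzero dosage at ≥ 2 distinct loci.

## Admixture ancestry

Genotype g at marker m given admixture proportion θ toward population A
is Binomial(2, p_m(θ)), p_m(θ) = θ·pA_m + (1−θ)·pB_m. The
log-likelihood — a sum of logs of terms affine in θ — is concave, so the
bounded scalar optimiser (`scipy.optimize.minimize_scalar`, xatol 10⁻⁶
on θ by default) plus an explicit check of both endpoints finds the
global maximum; boundary estimates are legal and reported as converged.
Ancestral frequencies are treated as known constants. Because reference
panels can carry frequencies of exactly 0 or 1, frequencies are clamped
into [ε, 1−ε] with ε = 10⁻³ by default; how the original analysis
smoothed such markers is unknown, so ε is exposed and the unclamped
likelihood (with −∞ only for genuinely impossible genotypes) is
available via ε = 0. Markers with missing genotypes are dropped per
individual; a panel with pA = pB at every called marker is rejected as
non-identifiable. Case/control ancestry balance is a two-tailed Welch
t-test on the per-individual estimates.

With the default synthetic panel (102 markers, mean frequency
difference δ ≈ 0.733) the estimator recovers θ = 0.70 with RMSE ≈ 0.04,
comfortably inside the < 0.1 the tests require, and matches a 10⁻⁴-step
grid search everywhere.

## Consequence calling

Variants are applied directly in CDS coordinates of complete toy
transcripts (start codon through stop, standard nuclear code only —
alternative starts are not recognised); genomic-to-CDS projection,
splicing and strand handling are deliberately out of scope, which keeps
the classification logic testable at desk scale. Classification is by
translation comparison (Biopython): any change destroying the initiator
ATG is a start loss; indels with length difference not divisible by 3
are frameshifts whose truncation position is the first stop in the
shifted frame (absent if none occurs before the transcript end, as
happens for late insertions); substitutions creating a premature stop
are nonsense with the truncation at the new stop codon; remaining calls
are synonymous / missense / in-frame indel. Multi-allelic records are
assumed decomposed to biallelic before calling. A truncation at residue
t of an L-residue protein removes (L − t + 1)/L of the chain; domains
are partitioned as retained (end < t), lost (start ≥ t) or partial
(straddling t). The damaging filter keeps truncating classes always and
missense only when PolyPhen-2 says probably damaging AND SIFT says
damaging/deleterious — the consensus rule for the candidate-gene
screen. Correctness is checked against a brute-force oracle that
mutates the CDS, retranslates and compares protein strings over
randomised transcripts and variants.

## Demographic comparisons

Group means are compared with a two-tailed t-test computable from raw
vectors or from printed (mean, SD, n) summaries; the two routes agree to
machine precision when the summaries come from the raw data. Both the
classical pooled-variance Student form and Welch (Satterthwaite df) are
implemented. The pooled form is the default for the reproduction layer:
on the published maternal-age summaries it gives p = 0.2561 → 0.256 as
printed, while Welch gives 0.2566 → 0.257 — consistent with the
analysis having used the classical test it names. Count variables
(gravidity, parity) are square-root transformed before testing; their
published p-values are not recomputable from printed summaries because
the transform precedes summarisation, so the reproduction report shows
them as informational only. The published case neonatal-weight SD
(1.59 kg at mean 1.69 kg) is implausibly large; the report recomputes
from the printed values as-is and annotates the anomaly. Significance
is declared at p < 0.05, strictly.

## Synthetic cohorts: what they emulate

The generator is a pure function of configuration and seed. Defaults
are the study conditions: 264 cases / 218 controls (discovery 76/43
plus follow-up 188/175); fourteen loci planted at the published
case/control frequency pairs, carried strictly heterozygously (each
sample het with probability 2f, so E[freq] = f) except the common FUT2
stop (f ≈ 0.37), which is drawn Binomial(2, f) so homozygotes occur at
Hardy–Weinberg rates; independent per-genotype missingness at 2% (the
study does not state its missing-call rate; 2% is a typical array/WES
joint-call figure and is a free parameter); a 102-marker AIMs panel
built by jittering per-marker frequency gaps around δ = 0.733 and
rescaling to hit the target; and individual θ drawn Normal(0.70, 0.08)
clipped to [0,1], bracketing the published group means (0.695/0.698)
and SDs (0.073/0.087).

Deliberately not emulated: linkage disequilibrium between loci,
relatedness, batch or platform effects, non-random missingness, and
uncertainty in the ancestral reference frequencies. Passing tests
therefore establish the correctness and calibration of the *methods*
under the stated sampling model — e.g. the one-sided burden test holds
its 5% type-I error across 1000 null cohorts at the study dimensions —
not robustness of the original study's conclusions to those real-data
complications.

## Problem sizes used in the test suite

The statistical property tests run at sizes chosen to give stable
checks at interactive cost: 1000 null cohorts (n_perm = 500 each,
exploiting the fixed-ranks reduction), 200 replicate cohorts for
frequency-concentration checks, 100 random individuals for the
MLE-vs-grid comparison, 1000 random transcript/variant pairs for the
consequence oracle, and 10K permutations wherever the published
analysis used 10K. Tolerances follow the statistics: 3 binomial SE for
Monte-Carlo quantities, printed precision for tabulated values.
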