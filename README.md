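# rareburden

Rare-variant candidate-gene burden analysis for preterm premature rupture
of membranes (PPROM) cohorts.

PPROM — spontaneous rupture of the fetal membranes before 37 weeks — is
the leading identifiable cause of preterm birth, and rare damaging
mutations in fetal genes that dampen innate immunity or defend against
microbes appear over-represented in affected neonates. `rareburden`
implements the analysis layer of that study design for case/control
cohorts of diploid genotypes at candidate loci:

- **Consequence calling** on candidate-gene coding sequences: nonsense,
  frameshift (with the truncation position at the first stop in the
  shifted frame), start-loss, missense/synonymous/in-frame classification,
  domain loss, and the damaging-variant filter (truncating classes plus
  missense called damaging by *both* PolyPhen-2 and SIFT).
- **Per-locus allele frequencies** over called chromosomes only — missing
  genotype calls shrink the denominator, never the numerator.
- **The across-loci burden test.** With per-locus paired differences
  d_l = p̂\_case,l − p̂\_control,l, the statistic is the Wilcoxon
  signed-rank sum W⁺ = Σ rank(|d_l|) over positive d_l (midranks for
  ties; zeros dropped, or ranked-but-excluded under the Pratt option).
  The null is generated by random sign flips of the d_l, with the
  add-one empirical p-value (r+1)/(B+1) and an exact 2^m enumeration
  oracle for m ≤ 20.
- **Ancestry estimation.** Individual admixture proportions θ in a
  two-way model (West African / European) by maximum likelihood over
  ancestry-informative markers: genotype at marker m is
  Binomial(2, θ·pA_m + (1−θ)·pB_m); the log-likelihood is concave in θ
  and maximised on [0,1] by bounded scalar optimisation.
- **Cohort statistics**: two-tailed t-tests from raw values or printed
  (mean, SD, n) summaries — pooled Student and Welch — with square-root
  transformation for count variables, plus detection power
  1 − (1 − f)^n, carrier/homozygote tallies, case-only locus scans and
  di-genic carrier identification.
- **Synthetic cohorts.** A seeded generator producing the study
  conditions end to end (264 cases / 218 controls, fourteen planted loci
  at the published frequency pairs, per-genotype missingness, a
  102-marker AIMs panel with δ ≈ 0.733, individual θ ≈ 0.70), written
  and read as standard VCF 4.2 + phenotype TSV.

The two fitted-model entry points follow the model/results idiom:
`AdmixtureModel(...).fit()` and `BurdenTest(...).fit()` return results
objects carrying estimates, diagnostics and `summary()`.

## Worked example

Run the burden test on the bundled published 14-locus frequency table,
then estimate ancestry for a simulated 76/43 cohort:

```python
import numpy as np
from rareburden import (BurdenTest, load_published_freqs,
                        AdmixtureModel, gen_panel, gen_aims, gen_thetas)

table = load_published_freqs()
result = BurdenTest.from_freq_frame(table).fit(
    n_perm=10_000, seed=1, alternative="two_sided", zero_policy="pratt")
print(result.summary())

panel = gen_panel(102, 0.733, seed=1)
thetas = gen_thetas(119, mean=0.70, sd=0.08, seed=2)
aims = gen_aims(thetas, panel, seed=3)
print(AdmixtureModel(aims, panel, is_case=np.arange(119) < 76).fit().summary())
```

```
Paired signed-rank burden test (sign-flip permutation null)
  W+ = 89 over 13 nonzero paired differences (max 91)
  empirical p = 0.0188  (10000 permutations, alternative=two_sided, zeros=pratt, seed=1)
  direction: 10 case-higher, 3 control-higher, 1 similar

Two-way admixture maximum-likelihood estimates
  individuals: 119   markers: 102   panel delta: 0.733
  theta mean +- SD: 0.703 +- 0.092
  cases:    0.703 +- 0.095 (n=76)
  controls: 0.703 +- 0.087 (n=43)
  Welch t = -0.012, df = 94.0, two-tailed p = 0.991
```

Ten of the fourteen loci have nominally higher alt-allele frequencies in
cases; the signed-rank statistic sits near the top of its range (89 of a
maximal 91) and the sign-flip null puts a two-sided empirical p of ~0.02
on that asymmetry. The simulated cohort shows what a well-balanced study
looks like: case and control mean ancestry within a fraction of a
standard deviation, Welch p ≈ 1.

The same operations are exposed on the command line
(`rareburden simulate|annotate|ancestry|burden-test|freqs|power|demographics|reproduce|run-all`);
`rareburden run-all --outdir out/` simulates a full study cohort and
writes every stage's table plus a manifest with the seeds and config
hash needed to re-run it identically.

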