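# Methods

## Model and estimators

Each variant is summarized by independent binomial allele counts
`x1 ~ Bin(n1, p1)` in cases and `x2 ~ Bin(n2, p2)` in controls, with
`n = 2 × subjects` for diploid data (allelic model; genotypic trend
tests, dominance codings and covariate adjustment are out of scope).
The maximum-likelihood MAF estimates `p̂g = xg/ng` feed three effect
sizes with the asymptotic (delta-method) variances:

| measure | estimator | SE used |
|---|---|---|
| risk difference | `d̂ = p̂1 − p̂2` | Wald `√(p̂1q̂1/n1 + p̂2q̂2/n2)`; score `√(p̄q̄(1/n1+1/n2))`, `p̄ = (x1+x2)/(n1+n2)` |
| Cohen's h | `ĥ = 2 asin√p̂1 − 2 asin√p̂2` | `√(1/n1 + 1/n2)` |
| odds ratio | `log ÔR = log[x1(n2−x2)] − log[x2(n1−x1)]` | `√(1/x1 + 1/(n1−x1) + 1/x2 + 1/(n2−x2))` |

Because `d(2 asin√p)/dp = 1/√(p(1−p))`, the arcsine transform cancels
the binomial variance `p(1−p)/n` exactly to first order — `Var(ĥ)`
depends only on the allele totals. This is the property everything
else builds on; it is asserted numerically across a MAF grid in the
test suite.

The hypothesis tests are two-sided normal tests of the ratio
estimate/SE. The RD test uses the pooled (score) SE, whose square is
identical to the Pearson chi-square of the 2×2 table; the OR test uses
the Wald SE. With the 1,926/2,938-subject worked-example counts these
conventions reproduce the three published p-values (4.88e-15 Wald-OR,
1.11e-15 pooled-RD, 4.00e-15 h) to order of magnitude, which is what
pinned the choice between pooled and unpooled forms.

**Zero cells and undefined values.** The OR and its SE are undefined
(`nan`, printed `NA`) whenever a table cell is zero; no Haldane/Anscombe
continuity correction is ever applied, because a corrected OR at a
zero-count rare variant is exactly the kind of unstable quantity the h
measure is meant to replace. `d` and `h` remain defined on the closed
unit square.

## Exact fallback

Asymptotic normality fails when expected minor-allele counts are tiny.
`test_variant` attaches a two-sided Fisher exact test whenever
`min(p̂1, p̂2) < 0.002` (configurable) or any cell is zero. The exact
p-value is the conditional hypergeometric tail: the sum of
probabilities of all tables (margins fixed) whose point probability is
at most the observed one, with a 1e-7 relative tolerance when comparing
near-tied probabilities in floating point. Both p-values are reported;
the genome-scan significance flag switches to the (adjusted) exact p
where the fallback fired. The implementation enumerates the
hypergeometric support directly via log-gamma sums — a vectorizable
form that makes exhaustive validation cheap — and is cross-checked in
the tests against scipy's independent implementation and against exact
integer-arithmetic enumeration for every table with margin total ≤ 60.

## Power and sample size

Balanced designs (`n` alleles per group, `n/2` subjects per arm). For
the two-proportion test of `H0: p1 = p2` against the OR-`c` alternative
(`p1 = c·p2/(c·p2 − p2 + 1)`):

    power = Φ( (Δ√n − z_{1−α/2}·√(2 p̄ q̄)) / √(p1q1 + p2q2) )
          + Φ( (−Δ√n − z_{1−α/2}·√(2 p̄ q̄)) / √(p1q1 + p2q2) ),

with `Δ = |p1 − p2|` and `p̄ = (p1 + p2)/2`. This "hybrid" form — null
(pooled) variance in the critical term, alternative variance in the
denominator — is the power function of the score test run at level α.
It reproduces the published 4,060-subject / 80% design example
(`min_sample_size` returns 4,058; the pure-Wald convention, also
exposed via `convention="wald"`, gives 4,042 — the example pins the
convention only to within ~20 subjects, so both are provided and the
hybrid is the default).

For the h test of `H0: h = 0` vs `|h| = δ`:

    power = Φ(|δ|·√(n/2) − z_{1−α/2}) + Φ(−|δ|·√(n/2) − z_{1−α/2}),

independent of `p2` given δ. At the same 4,060-allele design with
δ = h(OR = 3, p2 = 0.01) ≈ 0.1444 this gives 85.4% — the h-vs-OR power
ratio exceeds 1 across the entire rare-MAF grid (verified on
p2 ∈ [0.002, 0.05] × n ∈ [1,000, 10,000]).

Normal tails and quantiles go through `scipy.special.ndtr/ndtri`, which
keep relative accuracy deep in the tail, so α = 5e-8 (and far smaller)
quantiles are stable. `min_sample_size` does an exponential bracket
plus binary search over even totals and is tested against a linear
scan; the returned `n` satisfies `power(n) ≥ target > power(n − 2)`.

## Effect-size bands

Cohen's conventional 0.2/0.5/0.8 cuts were calibrated for proportions
near ½; at GWAS frequencies virtually no variant reaches 0.2, so the
shipped default bands are anchored to odds-ratio practice instead:
common variants |h| ≤ 0.075 / 0.15 (OR 1.2 / 1.5), rare variants
|h| ≤ 0.05 / 0.1 (OR 1.5 / 2), boundaries falling into the lower band.
The conventional cuts remain available as the named scheme `"cohen"`.

`derive_h_thresholds` re-derives h cuts from OR cuts by averaging
`h(OR, p2)` over a uniform MAF grid (step 0.001). Uniform averaging
over (0.05, 0.5] recovers the common-variant cuts well (0.078 / 0.177
vs 0.075 / 0.15); over (0.002, 0.05] it gives 0.068 / 0.125 rather than
the round 0.05 / 0.1 defaults — the published rare cuts evidently fold
in a downward rounding and/or a MAF spectrum weighted toward very rare
sites, which is why the derivation utility is *not* what classification
uses: the fixed published cuts are. The weighting question is the one
genuinely open design point here; uniform was chosen as the assumption-
free default and the discrepancy is documented rather than hidden.

## Quality control

`snp_qc` evaluates all four criteria per variant without short-
circuiting, so a bad variant lists every violated rule. Genotypes are
folded to the control-minor allele before MAF and HWE counting; missing
calls are excluded from allele/genotype counts while the call rate is
non-missing over all subjects. The HWE test is the conditional exact
test: given the allele counts, the heterozygote count has probability
∝ `n!/(nAA! nAa! naa!)·2^nAa`, and the two-sided p sums all outcomes no
more probable than the observed one (same point-probability rule and
tolerance as the Fisher test; a mid-p variant is deliberately not
offered). It is validated against exact-rational enumeration for every
genotype configuration with ≤ 50 subjects. Cohort heterogeneity
(criterion 4) reuses the package's own pooled two-proportion score test
between the first two control sub-cohorts and is skipped when only one
control cohort exists.

## Simulation design

The calibration protocol simulates what a pseudo case-control split of
a homogeneous control pool guarantees: truly null variants. Default arm
sizes are 1,480 and 1,458 subjects (the split sizes of the archival
control pool the protocol mirrors); control MAFs are drawn uniformly on
(0.05, 0.5) for the common-variant panel, and allele counts are
binomial under HWE. Per measure the report gives the grand mean of
estimates over replicate × variant cells (bias), the mean square (MSE),
and the fraction of p < 0.05 (type I error), with zero-cell log-OR
cells counted separately and excluded from its bias/MSE. The default
panel is 2,000 variants × 100 replicates = 200,000 cells, chosen so the
Monte-Carlo standard error on a 5% rejection rate is ≈ 0.0005 and on
the h MSE ≈ 2e-6 — far inside the bands being checked. Calibration
runs the asymptotic tests without the exact fallback, mirroring how
asymptotic size is assessed; a fallback-enabled variant can be composed
from `simulate_counts` + `test_variant` directly.

What the generator does **not** emulate: linkage disequilibrium,
population stratification, genotyping batch effects, and empirical MAF
spectra. Passing calibration here demonstrates the statistics behave as
their asymptotics promise under the binomial ideal — not that real
arrays are free of the inflation those forces cause (the variance-
stabilized h MSE, `1/n1 + 1/n2`, is spectrum-free by construction and
transfers; the log-OR MSE figures are spectrum-dependent and are
reported with their spectrum stated).

## Numerical and interface choices

- All randomness flows through one seeded `numpy` generator per run;
  reports carry the seed.
- Multiple-testing adjustment delegates to
  `statsmodels.stats.multitest` (Bonferroni, BH step-up) and is tested
  against the direct definitions; adjusted values are reported as
  monotone adjusted p-values, not reject lists. In a scan, the family
  size is the number of variants for every method; undefined p-values
  enter adjustment as 1 and are reported back as `NA`.
- Result TSVs are byte-stable: fixed column order, 6-significant-digit
  floats, scientific notation for p < 1e-4, and `<1e-300` instead of a
  p truncated to zero.
- VCF ingestion (cyvcf2) reads GT only, skips multi-allelic records
  with a warning, and takes cohort labels from an optional
  subject-to-cohort mapping since VCF cannot carry them.

## Known limitations

- Allelic tests assume HWE within groups; under strong departures the
  allele-level binomial variance understates the truth.
- Unequal-arm power formulas, mid-p exact tests, stratified
  (CMH-style) tests and gene-level burden/joint tests are not
  implemented.
- The OR-band/h-band agreement of the classification schemes holds at
  the MAF ranges the cuts were derived for; a variant classified on
  both scales can disagree near band edges or at atypical MAFs.
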