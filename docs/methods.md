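# Methods notes

This note records the models implemented, the defaults and why they were
chosen, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## Haplotype windows and codings

Windows are half-open 0-based marker-index intervals `[i, i + size)`
advanced by `step`, giving `floor((M - size)/step) + 1` windows; bp
coordinates stay 1-based (VCF convention). Haplotype alleles are the
distinct 0/1 strings spelled by the 2N chromosomes over the window, sorted
by ascending frequency with lexicographic tie-breaks so output is
deterministic under sample permutation. The centered coding
`z_k = copies − 2 p_k` uses the sample allele frequency, so each `z_k`
column is mean-zero by construction; we additionally subtract the empirical
column mean to cancel last-bit float rounding.

Missing or unphased genotypes are rejected at load with the offending
marker and sample named — the pipeline assumes upstream phasing and
filtering produced a clean panel. A minor-allele-frequency load filter is
available but off by default. Multi-allelic VCF records are rejected
rather than split: windows are defined over biallelic 0/1 codes.

Two HWE tests are provided. The chi-square test (1 df) compares genotype
counts with `n p²`, `2 n p (1−p)`, `n (1−p)²`. The exact test enumerates
heterozygote counts conditional on the allele counts and sums the
probabilities of configurations no more probable than the one observed
(two-sided), computed in log-gamma space for stability. For the reference
genotype counts (18, 241, 520) the chi-square p is ≈ 0.104 and the exact p
≈ 0.112; results near an HWE p of ~0.2 reported elsewhere for these counts
could not be reproduced by either method, so neither is asserted against
that value.

## Weighted association scan

Each record's residual variance is proportional to
`w_i = λ⁻¹(d_i + c)` with `λ = (1 − h²)/h²` and `d_i = (1 − r²_i)/r²_i`;
defaults `h² = 0.37` (birth-weight heritability in the emulated bull
panel) and `c = 0.9191` (the window explains at most ~8.1% of genetic
variance). The GLS normal equations are solved in closed form for
`X = [1 z_k]`; every haplotype allele is tested in its own single-regressor
model, with no joint multi-haplotype fit. Degrees of freedom for the
two-tailed t-test are `n − 2` (intercept plus slope); the convention is
configurable since different software differs here. Alleles below the
frequency floor (default 0.01) — or within the floor of fixation, where
the coding is numerically degenerate — are skipped, not merged. No
multiple-testing correction is applied by default (tag selection uses raw
p); Bonferroni is available behind a flag. Inputs are treated as
reliabilities r²; an `accuracy` option squares accuracy inputs first.

The tag is the globally most significant (window, allele) pair; p-value
ties break by larger |α|, then by leftmost window. The binary trait mode
(−1/+1 coding, identity weights) is exactly OLS on the coded trait.

## EHH and dating

EHH uses the identical-pair definition over carriers of the core allele,
computed by progressive refinement of the haplotype partition marker by
marker (O(N·M)); it is non-increasing outward by construction. The scan on
each flank stops at the first marker strictly below the threshold
(default 0.05 = 5% identity-by-descent probability). The decay span is
measured stop-marker to stop-marker ("entire length span"); the
alternative last-marker-at-or-above rule differs by at most one marker
spacing per side and is available behind a flag. A flank that never decays
is censored: an error by default, or the chromosome end with a censoring
flag when allowed.

Physical spans convert to map length at 1 cM per 1.23 Mbp unless a
per-marker cM map is supplied. The age formula is implemented as printed
in its source, `E[g] = 1 − ln(p)/r` (equivalently `1 + |ln p|/r`), which
includes a unit offset relative to the textbook `−ln(p)/r`; a `classic`
option drops the offset. At the spans of interest (r ≪ 1) the two differ
by a single generation and cannot be distinguished empirically.

Confidence intervals model generations-to-coalescence as Poisson(E[g]).
The default is 10⁶ Monte-Carlo draws with the quantile defined as the
smallest value whose empirical CDF reaches the level; an analytic mode
uses closed-form Poisson quantiles and a normal-approximation mode
(N(0, λ) error) is provided for comparison, never as default. When the
target level falls essentially on a Poisson CDF value (e.g. the 97.5%
point of λ = 13, CDF(20) = 0.97499), the Monte-Carlo quantile legitimately
flips between adjacent generations across seeds; tests therefore only
assert MC/analytic agreement where the CDF is several sampling standard
errors away from the level.

## Selection-coefficient scan

The recursion is the standard deterministic viability-selection map with
fitnesses 1, 1 − hs, 1 − s; h defaults to 0.5 (additive), consistent with
the additive phenotype distribution that motivates the scan. "Close to
fixation" is operationalized as p ≥ 0.99. Grids default to s ∈
{0.01, …, 0.50} and p₀ ∈ {0.01, …, 0.20}, both in steps of 0.01 — the step
is not dictated by the underlying analysis but matches the two-decimal
granularity of the reported range — with horizons of 60 and 100
generations. The recursion is monotone in s, p₀ and horizon, which the
tests exploit; drift, mutation and migration are deliberately out of scope
(stochastic sweeps live in the generator instead).

## Osteometry

The unit of analysis is one log-ratio per (fragment, measurement) record
by default; a per-specimen averaging policy (mean of log-ratios after the
log transform) is provided because fragment- and measurement-level counts
are often both quoted for the same assemblages. Welch's unequal-variance
t-test is the default (robust to the unbalanced group sizes typical of
archaeological assemblages); Student's pooled test is available. The
bundled reference-skeleton CSV is synthetic — plausible measurements for a
small 19th-century-type cow, clearly labelled as placeholders — because
the real reference's measurements are not published; only ratios taken
against the same reference are comparable, which is all the pipeline does.

## Synthetic-data generator

A forward-in-time Wright–Fisher simulation was chosen over coalescent
machinery so the selected locus evolves under exactly the same fitness
model as the deterministic recursion. Each generation, diploid parents are
sampled with probability proportional to their focal-locus fitness, and
each gamete recombines with a Poisson number of crossovers at the
panel-wide map length (uniform placement on the bp map, same 1.23 Mbp/cM
conversion as the dating module). The derived allele is introduced as a
single copy `age` generations before present; runs losing it (or missing a
configured present-day frequency window) restart, with the restart count
logged in the truth record so conditioning is visible. Neutral background
markers initialize at independent uniform(0.05, 0.95) frequencies with no
initial LD — the LD the pipeline detects is generated by the sweep itself.

Defaults (1,000 diploids = 2,000 chromosomes, 2,000 markers at 5 kbp,
s = 0.2, h = 0.5, age 60, Ne = 1,000) run in about a second and mirror a
dense-array chromosome segment. Phenotypes add polygenic noise scaled so
the focal window explains `qtl_share` (default 0.0809) of genetic
variance, and per-record deregression noise with variance `d_i` times the
genetic variance; reliabilities draw from Beta(38, 2) truncated to
[0.58, 0.98], honouring the minimum and mean of the emulated bull panel
(its quoted SD is larger than the feasible range of a reliability and is
not honoured). This makes the GLS weights exactly proportional to the true
residual variances, so estimator calibration (coverage, null uniformity)
is a meaningful test. Bone datasets draw log-ratios N(0, σ) and
N(δ, σ) with σ = 0.0932, chosen so that the closed-form standard error of
the mean difference at group sizes 33 and 89 is ≈ 0.019, matching the
reported precision of the two-period comparison.

What the generator does **not** emulate: demographic history (bottlenecks,
admixture, migration), array ascertainment, background LD, multi-locus
trait architecture, and linked selection beyond the single focal locus.
Passing tests therefore demonstrate internal correctness and calibration
of the estimators under the stated model, not robustness to the full
complexity of real cattle data.

## Problem sizes used in the test suite

Statistical suites scale the generator down to keep the default test run
fast while leaving the assertions meaningful: substitution-effect recovery
uses 200 replicates of n = 779 single-marker panels at tag frequency
0.178; null calibration pools ≥ 10,000 scan p-values over phenotype
replicates on a fixed 300-sample panel; tag recovery uses 50 replicates of
600-sample, 40-marker panels spanning 20 Mbp; dating rank-consistency uses
20 replicates each at true ages {20, 60, 150} generations on 600-chromosome,
1,000-marker (25 Mbp) panels. At these reduced population sizes the EHH
age estimate is rank-consistent but compressed for old sweeps (drift and
chance background homozygosity put a floor under the decay span), which is
why the suite asserts rank correlation rather than unbiasedness for the
oldest scenarios.

## Known limitations

- The dating point estimate inherits the compression above whenever the
  chromosome end censors the decay (young sweeps on short maps) or the
  panel is small; confidence intervals reflect only Poisson uncertainty in
  generations, not uncertainty in the span or in the bp-to-cM conversion.
- The exact HWE test enumerates heterozygote configurations; for very
  large counts the chi-square test is the practical choice.
- The association scan fits one allele at a time; colinearity between
  alleles of the same window is not modelled.
- Single-chromosome panels only; multi-chromosome inputs must be split
  upstream.
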