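# Methods

This note documents the statistical machinery, the defaults, and the
judgement calls behind `extirpa`, in the spirit of a model-description
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Record coding and period summaries

Occurrence tables are long-format rows (species, dataset, year, count,
optional abundance text and barcode-cluster id).  Two coding rules reflect
how historical compilations actually arrive:

* **Fixed-year substitution.** Some datasets report only a collecting
  interval; every record of such a dataset is coded with a single
  configured year (typically the interval mid-point).  The substitution is
  applied whenever the dataset matches, so an explicit year in such a
  dataset is also overridden — the dataset-level rule is the authority.
* **Abundance text.** Old lists sometimes state only "abundant" or
  "frequent".  Such records are scored as a fixed count (default 10,
  configurable), applied per record.

Period sums use inclusive year bounds for both the old (default 1923–1943)
and recent (default 1993–2013) windows; `n_between` covers years strictly
between the windows.  Malformed rows (negative or unparseable counts,
implausible years, blank species) are collected into a rejection report
and never silently dropped; a missing required *column* is a hard error.

## Status classification

Nine mutually exclusive categories partition the species list.  Two
annotation categories take precedence regardless of counts: *cryptic*
(known only from a barcode cluster) and *recently described* (formally
named after the old window closed).  The remaining seven are pure
predicates on (n_old, n_recent, n_between) with an abundance threshold
`min_abundant` (default 10): extinct (n_old ≥ 10, n_recent = 0), settler
(the mirror image), common (both positive, sum ≥ 10), plus four "unclear"
classes for sparse data.  The "common" rule requires *both* periods
positive; this is the only reading under which the seven predicates are
disjoint and exhaustive, and the property suite fuzzes that partition.

Species with zero counts everywhere and no flags raise an explicit
unclassifiable error listing the ids; voucher-only species must instead be
carried via the flags table (they land in the between-only class when they
have between-period records, and are otherwise the caller's problem — a
deliberate refusal to guess).

**Fisher validation.** Each extinct-category species is tested with a 2×2
Fisher exact test of its (n_old, n_recent) against the total individuals
per period.  Two-sided p sums all tables with point probability ≤ the
observed (the standard convention); a one-sided p in the direction of the
observed deviation is also reported.

**Rates.** The extinction rate is 100·E/(pool + E): the pool is estimated
from recent data only, so confirmed losses are added back to the
denominator.  Percentages round half away from zero.  The report offers a
low bound (identification-secure species only), a best estimate (all
extinct-category species), and a high bound that also counts every
not-seen-recently unclear species.

## Richness

**ICE.** Species found in ≤ `rare_threshold` (default 10) sampling units
are *infrequent*; with Q_j the number found in exactly j units,
N_infr = Σ j·Q_j, coverage C_ICE = 1 − Q₁/N_infr, m_infr the units holding
at least one infrequent species, and

    γ² = max[(S_infr/C_ICE)·(m_infr/(m_infr−1))·Σ j(j−1)Q_j / N_infr² − 1, 0],
    ICE = S_freq + S_infr/C_ICE + (Q₁/C_ICE)·γ².

Degenerate inputs (all infrequent species uniques, i.e. C_ICE = 0, or
fewer than two units with infrequent species) fall back to S_obs with an
explicit flag rather than an exception.  The reported dispersion is the
standard deviation of ICE over bootstrap resamples of sampling units
(units drawn with replacement, default 100 resamples).  A dispersion
across randomized *orderings* of the full unit set would be identically
zero — the estimator is ordering-invariant once all units are included —
so resampling is the meaningful notion of spread here.

**Accumulation curves** average cumulative richness over random unit
orderings; every ordering ends at S_obs.

**Cryptic asymptote.** Cumulative discoveries y over cumulative sequenced
individuals x are fit by least squares to y = a/(1 + b·x⁻ᶜ), a, b, c > 0
(optimized on the log scale, Levenberg–Marquardt, ~20 deterministic +
seeded random starts).  This parameterization is increasing, sigmoidal in
log x, and has horizontal asymptote a — the estimated total number of
lineages the discovery process can reach.  An all-zero y returns a = 0
with `converged=False`; decreasing y is an error.

## Community change

Bray–Curtis dissimilarity d(i,j) = 1 − 2·Σ min(xᵢ,xⱼ)/(Σxᵢ + Σxⱼ) between
year-samples with ≥ 300 recorded individuals (threshold configurable); the
triangle inequality is *not* asserted, since Bray–Curtis does not satisfy
it in general.  Two-dimensional non-metric multidimensional scaling is
delegated to scikit-learn's standard optimizer; this package owns only the
contract (rank preservation, seeded reproducibility) because ordination is
standard methodology, not this package's contribution.  Axis scores are
regressed (OLS) on year and total effort; a family×period table of
individuals is tested by Pearson chi-square without continuity correction
(all-zero families dropped with a warning); per-species period counts are
compared by Spearman correlation, including by default every species
non-zero in at least one of the two vectors.

## Phylogenetic signal

Trees are rooted with branch lengths (read as millions of years, but any
consistent unit works).  Polytomies are resolved randomly to zero-length
bifurcations under a seed before sister-clade statistics.

**ΣD and D.** Nodal trait values are estimated tips-to-root as unweighted
daughter means, and ΣD sums |left − right| over internal nodes.  Branch
lengths deliberately do not enter the nodal pass — they act only through
the Brownian null.  D scales the observed ΣD between null means:

    D = (ΣD_obs − mean ΣD_Brownian) / (mean ΣD_shuffle − mean ΣD_Brownian),

where the shuffle null permutes tip labels and the Brownian null simulates
a rate-1 Brownian trait on the branch lengths, thresholded so that exactly
the observed number of tips score 1.  p(D > 0) is the fraction of Brownian
ΣD ≥ observed; p(D < 1) the fraction of shuffle ΣD ≤ observed; both use
the add-one rule so Monte-Carlo p-values are never zero.  Calibration
(mean D ≈ 0 for Brownian-threshold traits, ≈ 1 for shuffled traits on
200-tip trees) is asserted in the acceptance suite rather than assumed.
The exact nodal-estimation variant used by other published implementations
is not restated here; this construction is documented and calibrated on
its own terms, and printed D values from other software are not treated as
reproduction targets.

**SES-MPD.** The mean pairwise patristic distance among the focal (extinct)
tips is compared with draws of equally many random tips; SES =
(obs − null mean)/null sd, and p = (#{null ≤ obs} + 1)/(n_runs + 1) for
the clumping side.  Patristic distances come from a single bottom-up
merge pass, cross-checked in the tests against an independent
path-traversal oracle.

## Phylogenetic logistic regression

Survival (1) vs local extinction (0) of the abundant classes is modeled as
Bernoulli with mean logit⁻¹(Xβ) and a working among-species correlation
exp(−α·d) in patristic distance.  Estimation solves a Firth-type penalized
quasi-score: the GEE quasi-score Xᵀ A^{1/2} R⁻¹ A^{-1/2}(y − μ) plus the
gradient of ½·log det(Xᵀ A^{1/2} R⁻¹ A^{1/2} X), with the linear predictor
clipped to ±btol (default 1000).  With R = I this is *exactly* Firth's
bias-reduced logistic regression (verified against an independent IRLS
oracle to 10⁻⁴), so separation-prone small extinct classes keep finite
estimates.  The inner solver is damped Newton with a Powell-hybrid root
fallback for rich interaction designs.

Numerical and inferential choices that matter:

* **Correlation cap.** Off-diagonal working correlations are capped at
  1 − 10⁻³: distinct species are never perfectly exchangeable, and tied
  tips (zero patristic distance) would otherwise make R singular at every α.
* **α estimation.** α is profiled on a 25-point log grid between
  0.05/d_max and 200/d̄; only α values where the penalized score equation
  actually has a solution are admissible (under very strong working
  correlation the marginal binary model loses identifiability and the
  score has no root).  Because α is weakly identified from a single
  realization, a finite α is accepted only if it improves the Gaussian
  pseudo-likelihood of the standardized residuals over the independence
  end of the grid by more than 1.92 (a χ²₁-scale margin); otherwise the
  fit reports α = ∞ and reduces to the Firth fit.  Without this guard,
  spuriously small α estimates shrink the Wald standard errors and the
  nominal-0.05 test rejects ~12 % of null datasets; with it the rejection
  rate is calibrated (the test suite checks ±0.03 over 200 replicates)
  while strongly clumped responses still select a finite α.
* **Wald inference** is conditional on the selected α; AICc =
  −2ℓ_pen + 2k + 2k(k+1)/(n−k−1) with k counting coefficients plus α when
  estimated, and ℓ_pen the Bernoulli log-likelihood plus the Firth penalty.
* **Design.** Ordered categorical predictors enter as consecutive integer
  scores (the coding the trait tables use); main effects are mean-centered
  before products are formed, so interaction columns are not trivially
  collinear with their parents.  Three interaction pairs
  (size:range, growth-form:color, range:color) are excluded by default as
  chronic convergence hazards in designs of this shape.
* **Stepwise selection** removes the largest-p non-significant term
  (threshold 0.05, configurable), interactions strictly before the main
  effects they contain; every visited model is AICc-scored and the removal
  log is part of the output.
* **Collinearity screen**: pairwise Spearman among main effects plus
  generalized variance-inflation factors from the inverse correlation
  matrix (each term carries one df, so GVIF = VIF here).

## Synthetic data

The generator is the package's source of ground truth, and its defaults
are the study conditions the analysis is meant for: 601 species,
log-series abundance weights (numpy's log-series with p = 0.995, a long
tail typical of tropical insect communities), old/recent period efforts
1418 and 7672 individuals (the ~5.4× asymmetry of a historical list
against modern monitoring), ~4 % of old-list species recorded only as
"abundant" text, and minority fractions of settlers (3.5 %),
between-period-only species (12 %), cryptic lineages (4.5 %) and
recently described species (4 %).

Mechanics worth knowing when interpreting test results:

* Trees are Yule or birth–death via dendropy, rescaled to a 100 My root
  depth; terminal branches are floored at 0.005·age because the sampler
  can stop exactly at a speciation event, and zero-length cherries are
  both biologically odd for distinct species and numerically hostile to
  the regression's working correlation.
* Ordered categorical traits evolve by a ±1 Markov walk along branches
  (default 0.02 expected changes per My — conserved, so clades share
  states); log wing size is Brownian.
* Extinction flags are Bernoulli draws from logit = intercept + Xβ
  (defaults make small, low-stature-host, host-specialist species more
  extinction-prone) plus an optional Brownian deviation scaled to unit
  tip variance times `phylo_sigma`.  Recovery and calibration experiments
  that check the *estimator* simulate with the deviation off, so the
  generating model matches the fitted marginal model; the pipeline default
  (`phylo_sigma = 0.5`) keeps residual phylogenetic clumping in the
  synthetic community itself.
* Period counts are multinomial over the participating species
  (residents + extinct in the old period; residents + settlers + cryptic +
  recently described in the recent one), so totals equal the configured
  efforts exactly; the "abundant"-text coding then replaces the drawn
  counts of the selected species with the coded value, which is precisely
  the distortion real compilations carry.  Extinct, settler and a
  configurable "abundant core" of residents receive the largest abundance
  weights — extinct species must be frequent in the old lists for the
  design to say anything.
* True categories are computed from the *coded* sums, so classifier
  agreement is audited against what the records actually say, cell by
  cell, not against latent roles.

What the generator does **not** emulate: detectability differences among
color patterns, taxonomic drift and synonymy across datasets, duplicate
reporting of single specimens across lists, spatial structure within the
site, and year-to-year population dynamics beyond the configured year
weights.  Passing tests therefore show the machinery is correct and
calibrated under the stated sampling model, not that any particular real
compilation satisfies that model.

## Problem sizes in the shipped checks

The test suite and acceptance script run the calibration experiments at
sizes chosen to keep the whole suite in the minutes range while leaving
Monte-Carlo error well inside the asserted tolerances: 200-tip trees ×
100 replicates for D calibration (null sizes 300), 300-tip trees ×
100–200 replicates for regression recovery and Wald calibration, 50 seeds
for the asymptote recovery, 999 tip randomizations for SES-MPD in the
pipeline default.  The D statistic's null size in the *pipeline* default
remains 10 000 permutations.
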