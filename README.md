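# extirpa

Tools for auditing **local extinction** from heterogeneous historical
occurrence records — the situation faced by anyone comparing an old
natural-history compilation (checklists, museum lots, anecdotal "abundant"
remarks) against modern standardized monitoring of the same site.  The
motivating use case is a tropical butterfly fauna surveyed in two widely
separated periods with a ~5× difference in effort, but every stage is
generic over long-format occurrence tables, a species trait table, and a
dated phylogeny.

The package answers four questions:

1. **Which species are plausibly extinct locally?**  Records are coded
   (fixed-year substitutions for undated museum lots; "abundant"/"frequent"
   remarks scored as a fixed count, default 10) and summed per species over
   an *old* and a *recent* period.  Each species lands in exactly one of
   nine abundance-status categories; the *extinct* category (≥ 10
   individuals in the old period, none in the recent one) is validated
   per species with a Fisher exact test of its period split against the
   overall effort split (n_old vs n_recent against N_old vs N_recent).
2. **Against what species pool?**  Richness of the recent fauna is
   estimated with the incidence-based coverage estimator over sampling
   units, ICE = S_freq + S_infr/C_ICE + (Q₁/C_ICE)·γ²_ICE, with randomized
   accumulation curves; the pool of still-undiscovered cryptic lineages is
   estimated as the asymptote *a* of a logistic-power fit
   y = a/(1 + b·x⁻ᶜ) to cumulative discoveries over sequenced individuals.
   The extinction rate is then 100·E/(pool + E) with low/best/high bounds.
3. **Did the community change?**  Bray–Curtis dissimilarities between
   year-samples, a non-metric ordination with axis-score regressions on
   year and effort, a family×period chi-square on individuals, and Spearman
   correlations of per-species counts between periods.
4. **Is extinction phylogenetically and ecologically selective?**  The
   D statistic for a binary trait (sister-clade difference sum ΣD scaled
   between tip-shuffling and Brownian-threshold null means), SES-MPD of the
   extinct tip set under tip-label randomization, and a phylogenetic
   logistic regression of survival on species traits (Firth-penalized
   estimating equations with among-species correlation exp(−α·d) in
   patristic distance, btol-bounded linear predictor, backward stepwise
   selection scored by AICc).

A fully seeded synthetic-data generator (`extirpa.synth`) produces dated
phylogenies, phylogenetically conserved traits, trait-linked extinction,
log-series communities sampled under unequal period efforts, and saturating
cryptic-discovery curves — with per-species ground truth, so every stage of
the pipeline can be audited against construction.

## Worked example

```python
import extirpa as ex

# 23 extinct species against a 390-species resident pool
r = ex.extinction_rate(23, 390)
print(r.percent, r.rounded_percent)            # 5.5690... 6

# the least extreme extinct-category species vs the overall effort split
f = ex.fisher_validate(10, 0, 1418, 7672)
print(f.p_two_sided)                           # 8.307e-09

# ICE on a small incidence matrix (5 species x 3 surveys)
import numpy as np
inc = np.array([[1,0,0],[0,1,0],[1,1,0],[1,1,1],[1,1,1]])
est = ex.ice_estimate(inc, n_perm=0)
print(est.s_obs, est.c_ice, est.ice)           # 5 0.8 7.03125
```

The first block says 23 locally lost species are 5.57 % (printed as 6 %) of
the estimated resident pool plus the losses.  The Fisher p (≈ 8×10⁻⁹) shows
that 10 old-period individuals with zero recent-period sightings is already
wildly inconsistent with the 1418:7672 effort split, so every species in
the extinct category clears p < 10⁻⁴.  In the ICE block, sample coverage
0.8 inflates the 5 observed species to an estimated 7.03.

Full pipeline from a config:

```sh
extirpa all --config config.yaml --seed 42 --out-dir out/
```

with a `config.yaml` such as

```yaml
simulate:            # or an `inputs:` block with records/tree/traits paths
  n_species: 300
params:
  min_abundant: 10
  n_perm_d: 10000
  mpd_runs: 999
  btol: 1000
```

writes `out/report.json` (census, Fisher validations, rate bounds, ICE,
asymptote, composition tests, D, SES-MPD, regression fit and removal log)
plus per-stage CSVs.

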