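# Methods

## Cohort model

A cohort is a cross-section of people aged 40 and over, each with integer
age, sex, a group label (`copd` cases vs `control`), outcome flags (3-year
death, prior-year hospitalization, confirmed smoker), and a binary vector
over an ordered catalog of chronic conditions. Exactly one catalog entry is
the index COPD diagnosis; comorbidity counts always exclude it. The COPD
case definition follows the EMR convention: at least two encounters coded
with an ICD-9 root in {490, 491, 492, 494, 496} (decimals match by 3-digit
root; the two encounters need not share a root). Five age brackets —
40–55, 56–65, 66–75, 76–85, >85, inclusive on both ends — partition the
age range; their midpoints (47.5, 60.5, 70.5, 80.5, and 90.5 with the open
bracket capped at 95) quantify between-bracket age distances.

The bundled 119-condition catalog is synthetic: the ~40 condition names
that appear in the published hub and elder-disease tables are real, the
remainder are placeholders, and only the index entry carries ICD-9 codes.
Thirteen conditions carry the elder-disease flag (cataract, degenerative
joint disease, diabetes, coronary artery disease, benign prostatic
hypertrophy, osteoporosis, dementia, depression, hearing loss, skin and
lung cancer, chronic renal failure, atherosclerosis).

## Edge test and network statistics

The pairwise association between two binary disease indicators is the phi
coefficient, φ = (ad−bc)/√((a+b)(c+d)(a+c)(b+d)), with p-value
P(χ²₁ ≥ n·φ²). Pairs involving a constant column are undefined and skipped
(counted and logged). Edges are those pairs with p ≤ α; α defaults to 0.01,
the conventional threshold under multiple correlation testing, with no
multiplicity correction by default (Benjamini–Hochberg and Fisher-exact
edge tests are flags). Negative edges are retained and count toward degree
and density; a `positive_only` flag restricts them. A disease with at
least one case is a node even when isolated — which is why a stratum in
which one catalog condition never occurs yields a 118-node network while
its counterpart yields 119.

Quartiles of the degree distribution use the nearest-rank (type-1)
convention; hubs are all nodes with degree ≥ the 75th percentile, ties
included, sorted by degree then prevalence then identifier. The hub degree
share is Σ(hub degrees)/2E. Heavy-tail diagnostics compare the maximized
log-likelihood of a discrete power law (zeta distribution, exponent fitted
by bounded scalar optimization on degrees ≥ 1) against a geometric fit
(MLE p = 1/mean); a positive difference flags a heavier-than-exponential
tail. Constant-degree networks are reported as degenerate without fitting.

Bootstrap confidence intervals resample persons (rows) with replacement —
never edges, which are derived statistics — rebuild the network per
replicate, and take percentile 2.5/97.5 bounds; B = 1000 by default,
deterministic for a fixed seed.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
population's clinical detail.

*Demographics.* Case ages are drawn by bracket (default shares
12/20/33/27/8%, the control column of the reference cohort's age table),
then uniformly within bracket (the open bracket truncated at 95); sex is
male with probability 0.70. Every control is a demographic clone of one
case, so the groups are exactly matched by construction.

*Diseases.* Person-level latent factors u ~ N(0, I_K), K = 3. Disease d is
present with probability Φ(λ_d·u + b_d + s_d(age_eff − 40)) given u, where
age_eff = age + Δ·1[case]. The marginal prevalence is
Φ((b_d + s_d(age_eff−40))/√(1+‖λ_d‖²)); `prevalence_closed_form` evaluates
the defining integral by 61-node Gauss–Hermite quadrature and is the
generator's ground truth in tests. The index condition is set by group
membership (1 for cases, 0 for controls) and excluded from the latent
model.

*Early aging.* Modelled as the pure age shift Δ: a case of age a draws
diseases as a control of age a + Δ would. Default Δ = 15 years, the
midpoint of the reported 10-to-20-year lag.

*Default disease parameters* are a deterministic function of catalog
position, chosen once to land on the reference cohort's printed margins:
prevalence at the reference age of 70 decays geometrically over a short
common head (40% → 2% across 20 conditions) and a long rare tail
(2% → 0.1%), spanning the reported 0.05–56% range and giving mean
comorbidity counts near 3.5 (controls) and 5.0 (cases); probit age slopes
cycle over 0.008–0.024 per year; each non-index disease loads on a single
factor (cycling) with magnitude decaying 1.0 → 0.25, so common diseases
are hub-prone and loading norm predicts downstream degree. Under these
defaults the full-cohort networks reproduce the reference pattern: ~1990
vs ~1760 edges, density 0.28 vs 0.26, degree medians 34 vs 30, ~30 hubs
with ~23 shared.

*Mortality.* 3-year death is Bernoulli with logit β₀ + ln(2.75)/10·age +
ln(1.09)·count + ln(1.65)·1[case]; β₀ is calibrated by bisection so the
mean predicted control death probability is 0.11 (the intercept is not
published; the control aggregate is). Smoking is an independent flag
(probabilities 0.21 cases / 0.07 controls); prior-year hospitalization is
descriptive only (4.6% / 0.3%).

What the generator does **not** emulate: sex-specific prevalence (e.g.
prostatic disease in women is not zeroed), longitudinal onset, negative
disease associations (all latent correlations are nonnegative — negative
edges arise only by chance), or the reference cohort's exact disease
identities beyond the named head. Passing tests therefore demonstrate that
the pipeline recovers known structure of this model class, not that it
validates any clinical claim.

## Stratified comparison and the aging lag

One network per (group, bracket) cell; empty cells are flagged, not fatal.
Two cells are "equivalent" on a metric when the comparison p-value exceeds
0.05 (mirroring the convention of comparing average degree between
networks with ANOVA):

* `degree` — one-way ANOVA on the two cells' node-degree samples (Welch t
  available);
* `density` — two-proportion Fisher test on (edges present, possible
  pairs);
* `elder_prevalence` — two-proportion Fisher test on pooled elder-disease
  cases over person×disease slots.

**Size matching.** Because edges are significance-thresholded, edge counts
grow with stratum size at fixed association strength, so raw cell
comparisons confound age structure with statistical power (a small old
stratum can mimic a large young one). By default the larger cell is
deterministically subsampled — the subsample seed depends only on the
cell, target size and grid seed, keeping comparisons symmetric — to the
smaller cell's person count and its network rebuilt before comparing.

**Lag.** For each COPD bracket, the matched control brackets are those
equivalent at p > 0.05; the lag is the bracket-midpoint difference of the
*closest-age* match (ties broken by larger p) — the smallest age shift
consistent with equivalence. Under Δ = 0 the same bracket almost always
matches, giving lag 0; under Δ = 15 at study scale the 56–65 bracket's
recovered lag has median 10–20 years across replicates, though a single
replicate can return 0 when the same-bracket ANOVA lands just above 0.05 —
lag estimates are bracket-resolution quantities and should be read as
replicate medians. The `elder_prevalence` metric has very high power at
study-scale denominators, so exact equivalence matches are rare there;
`degree` is the default lag metric.

## Prevalence, counts, mortality, smokers

Fisher's exact test is two-sided by minimum-likelihood summation of
hypergeometric probabilities (mid-p variant subtracts half the observed
table's probability); a zero margin returns p = 1 by convention.
Prevalence tables report per-disease numerators/denominators per group
(and bracket), with Fisher comparisons flagged significant at 0.05.
Comorbidity-count distributions use 5-year age bands, top-coded at ≥8
conditions, with normal-theory 95% CIs on group means. The mortality model
is a maximum-likelihood logit of death on age/10, comorbidity count and
the case indicator (statsmodels), with Wald CIs on the odds ratios;
suspiciously large coefficients or non-convergence raise a separation
error. The smokers subgroup extracts confirmed control-group smokers and
1:1 matches each to a randomly drawn case in the exact (age-year, sex)
cell, seeded; unmatched rows are reported and dropped.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng` seeded from the
  run seed; identical config + seed gives bit-identical cohorts.
* The bootstrap-coverage experiment is run in the regime where it is
  well-posed: 12 diseases in three strong factor blocks (loading 1.0,
  prevalence 0.25, near-zero age slope), where every true edge is
  decisively significant at the replicate size and the large-n mean degree
  is a stable target. Outside that regime the statistic is not n-stable
  (weak pairs keep crossing the threshold as n grows) and percentile
  intervals for threshold-count statistics are median-biased upward —
  a known limitation of bootstrapping significance-thresholded networks,
  worth keeping in mind when reading the B = 1000 intervals on real-data
  sized strata.
* Test problem sizes: study-scale checks use 20,000–27,617 per group;
  distributional unit checks use 2,000 per group; oracle sweeps enumerate
  all 2×2 tables with n ≤ 40 and brute-force all-pairs networks on
  7-disease catalogs.

## Known limitations

* The ANOVA's sampling unit is the node degree; degrees within a network
  are dependent, so the equivalence p-values are heuristic (as in the
  original convention), not exact.
* Bracket midpoints quantize the lag to multiples of ~10 years; the >85
  midpoint (90.5, capped at 95) is arbitrary.
* The phi χ² p-value is asymptotic; for very rare diseases in small strata
  the Fisher-exact edge option is preferable but quadratically slower.
* Negative-edge conventions in published link counts are ambiguous; both
  polarities are counted here, with a flag to restrict.
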