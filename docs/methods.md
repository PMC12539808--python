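# Methods

## The model

The Proactive Conservation Index treats conservation priority as a
relative, cohort-referenced composite of future threat exposure and trait
sensitivity.  For a cohort of species:

1. each raw variable is log1p-transformed (`ln(1 + x)`) unless configured
   otherwise, because exposure proxies and traits (range size, body mass,
   human density) are right-skewed over orders of magnitude and a linear
   min-max scale would otherwise be dominated by a few outliers;
2. each variable is min-max normalised within the cohort,
   `fs(x) = (x − min x)/(max x − min x)`;
3. variables whose large values reduce priority (range size, brood size,
   protected-range proportion) are reflected, `x → 1 − x`, so every scaled
   variable points the same way;
4. each threat t_i is coupled with the modifier traits v_j through
   weighted interaction products `r_i = Σ_j z_ij (t_i ⊙ v_j)`; a threat
   with no modifiers passes through as `r_i = t_i`;
5. the score is `p = fs(Σ_i w_i fs(r_i) / Σ_i w_i)`.

Assumptions worth keeping in view: the index is *relative* — a score of
0.8 means nothing outside its scaling cohort; threats and modifiers
interact multiplicatively, so a species with zero exposure to a threat
receives no penalty from a sensitising trait, and vice versa; and the
double re-scaling makes scores invariant to positive rescaling of all w_i
or of any single threat's z row, so only weight ratios are meaningful.

### Interaction-weight reading

The interaction step admits two readings of how z_ij enters: as a
multiplier, `z_ij (t_i ⊙ v_j)` (the default), or as an exponent,
`t_i ⊙ v_j^z_ij` (`interaction_mode="power"`).  The multiplicative form
is the default because it is the one under which proportional rescaling of
weights provably leaves scores unchanged — the documented behaviour of the
weighting scheme; the power form is kept switchable behind the same code
path for users who want diminishing-returns modifiers.

### Default variable set

`pcindex.simulate.default_specs()` encodes the default land-vertebrate
partition: seven threats (climate-extreme exposure, land-use exposure,
invasion exposure, human density, inverted range size, inverted protected
proportion, artificial-habitat intolerance) and two modifiers (body mass,
inverted brood size) applied to every threat.  This partition is a
reconstruction of common usage, not a law: every element is configurable
per variable via `VariableSpec`.  Body mass defaults to `direct`
everywhere, including amphibians — small-bodied amphibians are reported to
face *higher* risk, and users studying amphibians alone may flip the
direction to `inverted` for that cohort.

### Scaling cohorts

Scores default to within-class scaling (`cohort="class"`): a reptile's
score is relative to other reptiles.  `cohort="global"` pools everything;
a callable cohort rule is accepted for custom strata.  Cohorts with fewer
than two species cannot be min-max scaled and are reported and skipped,
never silently dropped.  Degenerate variables (constant within a cohort)
scale to all zeros with a `ConstantVariableWarning` — a constant carries
no ranking information, and zeros keep the pipeline total rather than
producing NaN.

### Data hygiene

Artificial-habitat intolerance scores habitat-suitability labels
suitable → 0, marginal → 0.5, absent/unassessed → 1.  Missing trait values
are imputed by the family median, never across families; a family with no
observed value is a hard error rather than a silent fallback to a global
median.  Tables with remaining missingness never enter the pipeline.

## Downstream analyses

**Red List agreement.** Categories are encoded LC=1 … CR=5; DD and NE
carry no rank and are excluded from correlations (but are summarised in
the per-category distributions — scoring unassessed species is part of
the index's point).  Spearman rho uses average ranks for ties; p-values
use the t-approximation for n > 10 and an exact full-enumeration
permutation test for n ≤ 10.  The future-criteria subset keeps threatened
species assessed under criteria A3 or E plus all LC/NT species;
threatened species with no recorded criteria are dropped from the
threatened side and logged.

**Proportion threatened and the ecoregion GLM.** Threatened means
VU/EN/CR; DD/NE are excluded from numerator *and* denominator.  The GLM is
binomial with a logit link, fitted by IRLS on (threatened, not-threatened)
counts via statsmodels; when only proportions are available the fit is
unweighted quasi-binomial (`scale="X2"`) and the summary flags that its
standard errors are not comparable to count-weighted ones.  Separation and
non-convergence raise errors with the deviance trace.  Response residuals
(observed − fitted proportion) are emitted raw; for mapping, the
signed-log transform `sign(r)·ln(1 + |r|/s)` (default scale s = 1) is odd,
monotone and zero-preserving, so region orderings are unchanged.

**Quartile cross-tabulation.** Family quartiles use linear-interpolation
sample quantiles (numpy's default), with bins assigned by `searchsorted`
on the 25/50/75% cuts so tied values always share a quartile; `{1..8}`
maps to `{1,1,2,2,3,3,4,4}`.  Quartiles can be computed pooled or within
class strata; strata with fewer than four families are skipped with a
warning.  Agreement is the fraction of families in the same quartile on
both measures; the maximally discordant list pairs Q4-on-one with
Q1-on-the-other.

**Aggregation.** Ecoregion means/sums count a species fully in every
region its range overlaps (no area weighting).  Tree node averaging
assigns each internal node the mean of its descendant *tips*; the
child-node-mean alternative differs on unbalanced trees and is not used.
Branch lengths are ignored — the computation is topology-only.

**Weight sensitivity and optimisation.** The sweep recomputes the index
with one variable's weight set to each grid value (default 0.1/1/10,
configurable to a 0–10 ramp) while all others stay at 1; modifier sweeps
move all of that modifier's z entries together.  Optimisation maximises
tie-corrected Spearman rho against an external reference via Nelder–Mead
on log threat weights (positivity by construction), with the all-ones
point plus Latin-hypercube restarts in [0.1, 10]; `n_starts=5`,
`maxiter=200` and `seed=1` by default, all configurable.  Because the
baseline is always a start, the achieved rho never falls below the
all-ones baseline; returned weights are normalised to mean 1 since only
ratios matter.  The objective is piecewise constant in the weights (ranks
change discretely), which is why a derivative-free simplex with restarts
is used rather than a gradient method.

**Clustering.** Operates on the oriented, scaled variable matrix (the
pipeline's post-scaling, pre-interaction stage).  Complete linkage on
Euclidean distances by default (ward/average/single available), cut by
`maxclust`.  Cluster ids are canonicalised by lexicographic centroid
order so labels do not depend on species order; exact centroid ties fall
back to cluster size.  WSS is computed for k = 1..k_max along cuts of one
dendrogram and is non-increasing by construction; the elbow helper
(maximum distance to the chord) is advisory only — k remains the
analyst's choice.

## The synthetic community generator

`simulate_species` emulates the statistical shape of real inputs, not
their biology: lognormal traits (body mass meanlog 4, sdlog 2; brood size
1, 0.8; range size 9, 3 — spanning orders of magnitude, in grams /
offspring / km²), Beta-distributed exposure proportions (climate and land
use Beta(2, 5), invasion Beta(1.5, 6)), lognormal human density (3, 1.5),
Beta(1.2, 8) protected proportion, and multinomial habitat labels
(15% suitable / 15% marginal / 70% absent).  Taxonomy is nested (40
families in 4 classes by default); regions are Bernoulli memberships with
per-region inclusion probabilities Beta(2, 6), every species guaranteed
at least one region; the tree is a seeded pure-birth simulation
(topology is all that downstream code uses).

Ordinal categories come from a proportional-odds model on the z-scored
latent index computed under the generator's true weights: category =
bin(slope·z + logistic noise), with cutpoints at the quintiles of the
realised latent-plus-noise score so the marginal category distribution
stays near-uniform at any slope.  Slope 0 gives independence; slope → ∞
gives a deterministic monotone binning.  The default slope of 0.7 was
calibrated by Monte-Carlo (n = 5000, five seeds) so the realised Spearman
correlation between index and ordinal categories falls in the moderate
band (≈ 0.33–0.36) observed for real vertebrate faunas.  A
`dd_ne_fraction` (default 0.13, the approximate share of Data Deficient
vertebrates) is relabelled DD/NE at random.

What passing tests on this generator do **not** show: real exposures are
spatially autocorrelated and correlated with each other and with traits;
real Red List categories depend on criteria the index does not see; real
phylogenies carry trait covariance.  The generator draws everything
independently, so tests demonstrate correctness of the computations and
calibration of the statistics, not ecological validity of the index.

## Numerical choices and problem sizes

All arithmetic is double precision; score comparisons in tests use
1e-9 (1e-12 against the straight-line transcription oracle).  Min-max
extremes are exact in IEEE arithmetic ((max−min)/(max−min) = 1, 0/(…) =
0), so the bound guarantees are asserted with `==`.  The test suite runs
its simulation-based checks at deliberately modest sizes — communities of
200–500 species, 50 optimisation replicates, 1000 GLM null replicates —
chosen as the smallest sizes at which the statistical assertions have
comfortable margins.

## Known limitations

The index inherits the limits of its inputs: threats without global
projections (disease, overexploitation beyond the human-density proxy)
are invisible to it; exposure proportions are taken within current
ranges, ignoring range shifts; and the default weights express no
ecological judgement — users are expected to set or optimise weights for
their context rather than accept equal weighting as truth.  The weight
optimiser finds a local optimum of a non-smooth objective; restarts
mitigate but do not guarantee globality.
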