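# pcindex — the Proactive Conservation Index

Conservation prioritization is usually anchored to past and present
declines: the IUCN Red List, the most widely used scheme, mostly encodes
what has already happened to a species.  `pcindex` implements the
**Proactive Conservation Index (PCI)**, a continuous score in [0, 1] built
instead from *projected future* pressures — extreme-temperature exposure,
anthropogenic land-use conversion, biological invasions, human population
density — combined with traits that modulate a species' sensitivity to
them (body mass, brood size, range size, protected-range coverage,
intolerance of artificial habitats).  The package is aimed at
macroecologists and conservation planners who want a transparent,
weight-configurable priority ranking that also covers Data Deficient and
never-evaluated species, which category-based schemes must leave out.

## The index

For each variable x the pipeline applies a log1p transform (most inputs
are right-skewed over orders of magnitude) and min-max normalisation

    fs(x) = (x − min x) / (max x − min x),

reflecting (x → 1 − x) variables whose large values *reduce* priority
(range size, brood size, protected proportion).  Each scaled threat t_i is
then coupled with the scaled modifier traits v_j through weighted
interaction products

    r_i = Σ_j z_ij (t_i ⊙ v_j),

and the index is the re-scaled weighted mean over the n threats

    p = fs( Σ_i w_i fs(r_i) / Σ_i w_i ).

Scores are *relative to a scaling cohort* (by default, species of the same
taxonomic class): within a cohort the species least threatened on every
variable scores exactly 0 and the most threatened exactly 1.  Only weight
ratios matter — rescaling all w_i, or the z_ij of any single threat, by a
positive constant leaves scores unchanged.

Around the index the package implements the companion analyses: ordinal
Red List agreement (Spearman, per-category distributions, family quartile
cross-tabulation), an ecoregion-level binomial-logit GLM of threatened
proportion on mean PCI with signed-log residuals, taxonomic / spatial /
phylogenetic aggregation, one-weight-at-a-time sensitivity sweeps,
rank-matching weight optimisation, and hierarchical clustering of threat
profiles — plus a fully seeded synthetic community generator so everything
is testable offline.

## Worked example

```python
from pcindex import ProactiveConservationIndex
from pcindex.simulate import worked_fixture

table, expected, weights = worked_fixture()
results = ProactiveConservationIndex(table, weights=weights).fit()
print(results.scores)
```

```
species_id
sp1    0.000000
sp2    1.000000
sp3    0.776683
Name: pci, dtype: float64
```

The fixture has three species: climate exposure rises 0 → 0.5 → 1 across
them while land-use exposure falls 1 → 0.5 → 0, and body mass (10 / 100 /
1000 g) modifies both threats.  sp1 is the cohort's oriented minimum once
mass is taken into account, so it scores exactly 0; sp2's mid-range
exposures combined with moderate mass make it the aggregate maximum
(score exactly 1); sp3 lands at 0.777.  `results.summary()` prints the
per-cohort score table, and `results.scaled_variables` /
`results.interaction_products` expose the intermediates.

A larger session, end to end from the shell:

```sh
pci simulate --n-species 500 --seed 7 --output demo/
pci compute  --input demo/species.csv --config demo/config.yaml \
             --cohort class --output demo/scores.csv
pci compare  --scores demo/scores.csv --labels demo/labels.csv \
             --output demo/comparison/
```

The final command prints, for the default synthetic community,
`Spearman rho = 0.3459 (p = 1.13e-13, n = 435)` — moderate positive
agreement with the ordinal Red List encoding, with the per-category score
distributions written to `demo/comparison/category_distribution.csv`.

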