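"""Synthetic species communities with the structure the analyses assume.

Real inputs to the index are per-species threat exposures (proportions of
the range under extreme temperatures, anthropogenic land use, high invasion
threat; human population density over the range) and traits (body mass,
brood size, range size, protected-range proportion, artificial-habitat
intolerance), plus Red List categories, ecoregion memberships and a
phylogeny.  The generator emulates their statistical shape: traits are
lognormal (right-skewed over orders of magnitude), exposures are Beta in
[0, 1], ordinal categories follow a proportional-odds model on the latent
index computed under known "true" weights — so the strength of association
between the index and the Red List is a tunable, known quantity — and the
tree is a seeded pure-birth simulation.

Everything is deterministic given the seed (numpy Generator, PCG64).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .variables import ValidationError, VariableSpec, VariableTable, WeightScheme

__all__ = ["SimulationConfig", "SimulatedData", "default_specs",
           "simulate_species", "worked_fixture", "WORKED_FIXTURE_SCORES"]

CLASS_NAMES = ("amphibia", "aves", "mammalia", "reptilia")


def default_specs() -> list[VariableSpec]:
    """The default 7-threat / 2-modifier variable set for land vertebrates.

    Threats: proportion of range under extreme temperatures, under
    anthropogenic land use, under high invasion threat; human population
    density; range size and strictly-protected range proportion (both
    inverted — large values reduce priority); artificial-habitat
    intolerance.  Modifiers: body mass (direct) and brood size (inverted —
    large broods buffer against threats).  This partition is a
    reconstruction of common practice and is fully configurable.
    """
    return [
        VariableSpec("climate_exposure", "threat", "direct", "log1p", proportion=True),
        VariableSpec("landuse_exposure", "threat", "direct", "log1p", proportion=True),
        VariableSpec("invasion_exposure", "threat", "direct", "log1p", proportion=True),
        VariableSpec("human_density", "threat", "direct", "log1p"),
        VariableSpec("range_km2", "threat", "inverted", "log1p"),
        VariableSpec("protected_proportion", "threat", "inverted", "log1p", proportion=True),
        VariableSpec("habitat_intolerance", "threat", "direct", "log1p"),
        VariableSpec("body_mass_g", "modifier", "direct", "log1p"),
        VariableSpec("brood_size", "modifier", "inverted", "log1p"),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the community generator; defaults describe a plausible fauna.

    Lognormal (meanlog, sdlog) parameters keep traits strictly positive and
    right-skewed over orders of magnitude; Beta (alpha, beta) parameters
    keep exposures in [0, 1] with most mass at moderate exposure.
    ``category_slope`` scales the proportional-odds association between the
    latent index (under ``true_weights``) and the ordinal category: 0 means
    independence, large values a deterministic monotone binning.
    """

    n_species: int = 500
    n_classes: int = 4
    n_families: int = 40
    trait_lognormal_params: dict = field(
        default_factory=lambda: {
            "body_mass_g": (4.0, 2.0),
            "brood_size": (1.0, 0.8),
            "range_km2": (9.0, 3.0),
        }
    )
    exposure_beta_params: dict = field(
        default_factory=lambda: {
            "climate_exposure": (2.0, 5.0),
            "landuse_exposure": (2.0, 5.0),
            "invasion_exposure": (1.5, 6.0),
        }
    )
    density_lognormal: tuple = (3.0, 1.5)
    protected_beta: tuple = (1.2, 8.0)
    habitat_probs: tuple = (0.15, 0.15, 0.70)  # suitable, marginal, absent
    true_weights: WeightScheme | None = None
    category_slope: float = 0.7
    category_cutpoints: tuple | None = None
    dd_ne_fraction: float = 0.13
    n_regions: int = 20
    include_tree: bool = True
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_species, self.n_classes, self.n_families, self.n_regions) < 1:
            raise ValidationError("all counts must be positive")
        if self.n_species < 2 * self.n_classes:
            raise ValidationError("need at least 2 species per class on average")
        if not 0 <= self.dd_ne_fraction <= 1:
            raise ValidationError("dd_ne_fraction must be in [0, 1]")
        for name, (a, b) in self.exposure_beta_params.items():
            if a <= 0 or b <= 0:
                raise ValidationError(f"invalid Beta parameters for {name}")
        for name, (_, sd) in self.trait_lognormal_params.items():
            if sd <= 0:
                raise ValidationError(f"invalid lognormal sd for {name}")
        if self.category_slope < 0:
            raise ValidationError("category_slope must be >= 0")
        if self.category_cutpoints is not None:
            cp = list(self.category_cutpoints)
            if len(cp) != 4 or any(a >= b for a, b in zip(cp, cp[1:])):
                raise ValidationError("cutpoints must be 4 strictly increasing values")


@dataclass
class SimulatedData:
    """One synthetic community: inputs for every downstream analysis."""

    table: VariableTable
    labels: pd.DataFrame  # species_id-indexed: category, criteria
    membership: pd.DataFrame  # long: species_id, region_id
    tree: dendropy.Tree | None
    latent: pd.Series  # the index under the generator's true weights


def _categories_from_latent(
    latent: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Proportional-odds draw: category = bin of slope*z(latent) + logistic noise."""
    z = (latent - latent.mean()) / (latent.std() or 1.0)
    eta = cfg.category_slope * z
    star = eta + rng.logistic(size=len(latent))
    if cfg.category_cutpoints is not None:
        cuts = np.asarray(cfg.category_cutpoints, dtype=float)
    else:
        # quintile cutpoints of the realised latent-plus-noise score keep
        # the marginal category distribution near-uniform at any slope
        cuts = np.quantile(star, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(cuts, star, side="left") + 1


def simulate_species(config: SimulationConfig | None = None) -> SimulatedData:
    """Draw one synthetic community; deterministic given ``config.seed``."""
    cfg = config if config is not None else SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_species
    ids = pd.Index([f"sp{i:05d}" for i in range(n)], name="species_id")

    # taxonomy: families nested in classes, species spread over families
    fam_of_species = rng.integers(0, cfg.n_families, size=n)
    class_of_family = np.arange(cfg.n_families) % cfg.n_classes
    class_names = [CLASS_NAMES[i % len(CLASS_NAMES)] + ("" if i < len(CLASS_NAMES) else str(i))
                   for i in range(cfg.n_classes)]
    families = pd.Series([f"fam{f:03d}" for f in fam_of_species], index=ids)
    classes = pd.Series(
        [class_names[class_of_family[f]] for f in fam_of_species], index=ids
    )

    cols = {}
    for name, (a, b) in cfg.exposure_beta_params.items():
        cols[name] = rng.beta(a, b, size=n)
    mu, sd = cfg.density_lognormal
    cols["human_density"] = rng.lognormal(mu, sd, size=n)
    for name, (mlog, slog) in cfg.trait_lognormal_params.items():
        cols[name] = rng.lognormal(mlog, slog, size=n)
    a, b = cfg.protected_beta
    cols["protected_proportion"] = rng.beta(a, b, size=n)
    habitat = rng.choice([0.0, 0.5, 1.0], size=n, p=list(cfg.habitat_probs))
    cols["habitat_intolerance"] = habitat

    specs = default_specs()
    values = pd.DataFrame(cols, index=ids)[[s.name for s in specs]]
    table = VariableTable(values, specs, class_labels=classes, family_labels=families)

    # latent index under the generator's true weights, pooled cohort so a
    # single latent scale drives the ordinal categories
    from .index import ProactiveConservationIndex

    true_w = cfg.true_weights or WeightScheme.equal(table)
    latent = ProactiveConservationIndex(
        table, weights=true_w, cohort="global"
    ).fit().scores.rename("latent")

    ranks = _categories_from_latent(latent.to_numpy(), cfg, rng)
    cat = np.array(["LC", "NT", "VU", "EN", "CR"])[ranks - 1]

    criteria = np.array([""] * n, dtype=object)
    threatened = np.isin(cat, ["VU", "EN", "CR"])
    u = rng.random(n)
    pool = np.array(["A2", "B1", "B2", "C1", "D"])
    other = pool[rng.integers(0, len(pool), size=n)]
    criteria[threatened] = other[threatened]
    criteria[threatened & (u < 0.20)] = "A3"
    criteria[threatened & (u >= 0.20) & (u < 0.25)] = "E"

    n_ddne = int(round(cfg.dd_ne_fraction * n))
    if n_ddne:
        pick = rng.choice(n, size=n_ddne, replace=False)
        dd = pick[: max(1, int(round(0.75 * n_ddne)))]
        ne = pick[len(dd):]
        cat = cat.copy()
        cat[dd] = "DD"
        cat[ne] = "NE"
        criteria[pick] = ""
    labels = pd.DataFrame({"category": cat, "criteria": criteria}, index=ids)

    # region membership: per-region inclusion probability, every species
    # guaranteed at least one region
    region_ids = [f"eco{r:03d}" for r in range(cfg.n_regions)]
    incl = rng.beta(2.0, 6.0, size=cfg.n_regions)
    M = rng.random((n, cfg.n_regions)) < incl[None, :]
    lonely = ~M.any(axis=1)
    M[lonely, rng.integers(0, cfg.n_regions, size=int(lonely.sum()))] = True
    rows, cols_idx = np.nonzero(M)
    membership = pd.DataFrame(
        {"species_id": ids[rows], "region_id": np.array(region_ids)[cols_idx]}
    )

    tree = None
    if cfg.include_tree:
        taxa = dendropy.TaxonNamespace(list(ids))
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=n,
            taxon_namespace=taxa,
            rng=random.Random(int(rng.integers(2**31))),
        )

    return SimulatedData(
        table=table, labels=labels, membership=membership, tree=tree, latent=latent
    )


#: Hand-computed scores of the 3-species worked fixture (straight-line
#: evaluation of the transform -> scale -> interact -> aggregate pipeline).
WORKED_FIXTURE_SCORES = np.array([0.0, 1.0, 0.7766827785756892])


def worked_fixture() -> tuple[VariableTable, np.ndarray, WeightScheme]:
    """The fixed 3-species hand-oracle fixture.

    Climate exposure [0, 0.5, 1] and land use exposure [1, 0.5, 0] as
    threats, body mass [10, 100, 1000] g as the single modifier of both,
    all weights 1.  Byte-identical across calls; expected scores
    ``WORKED_FIXTURE_SCORES`` were evaluated by hand from the pipeline
    definition.
    """
    ids = pd.Index(["sp1", "sp2", "sp3"], name="species_id")
    values = pd.DataFrame(
        {
            "climate_exposure": [0.0, 0.5, 1.0],
            "landuse_exposure": [1.0, 0.5, 0.0],
            "body_mass_g": [10.0, 100.0, 1000.0],
        },
        index=ids,
    )
    specs = [
        VariableSpec("climate_exposure", "threat", "direct", "log1p", proportion=True),
        VariableSpec("landuse_exposure", "threat", "direct", "log1p", proportion=True),
        VariableSpec("body_mass_g", "modifier", "direct", "log1p"),
    ]
    table = VariableTable(
        values, specs, class_labels=pd.Series(["reptilia"] * 3, index=ids)
    )
    weights = WeightScheme(
        threat_weights={"climate_exposure": 1.0, "landuse_exposure": 1.0},
        interaction_weights={
            ("climate_exposure", "body_mass_g"): 1.0,
            ("landuse_exposure", "body_mass_g"): 1.0,
        },
    )
    return table, WORKED_FIXTURE_SCORES.copy(), weights
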