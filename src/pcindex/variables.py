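"""Species-by-variable tables and weighting schemes for the Proactive Conservation Index.

The index is computed from a table of per-species variables, each of which is
either a *threat* (an exposure-side quantity such as the proportion of the
range under extreme temperatures) or a *modifier* (a trait that modulates
sensitivity to threats, such as body mass).  Every variable carries metadata
describing how it enters the pipeline: whether it is log1p-transformed before
scaling, and whether large values increase priority (``direct``) or decrease
it (``inverted``, e.g. range size — a large range reduces priority, so the
scaled variable is reflected as 1 - x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = frozenset({"threat", "modifier"})
DIRECTIONS = frozenset({"direct", "inverted"})
TRANSFORMS = frozenset({"log1p", "none"})

#: Habitat-suitability labels for artificial environments and the
#: intolerance score they map to: species that can use artificial habitats
#: are less exposed to land conversion.
HABITAT_SCORES: Mapping[str, float] = {
    "suitable": 0.0,
    "marginal": 0.5,
    "absent": 1.0,
    "unassessed": 1.0,
}


class ValidationError(ValueError):
    """Raised when an input table, spec or weight scheme violates its contract."""


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one column of a species table.

    Parameters
    ----------
    name : str
        Column name, unique within a table.
    role : {"threat", "modifier"}
        Whether the variable enters the index as an exposure (outer sum of
        the interaction step) or as a sensitivity modifier (inner sum).
    direction : {"direct", "inverted"}
        ``inverted`` variables are reflected (x -> 1 - x) after scaling, so
        that large values always mean higher priority.
    transform : {"log1p", "none"}
        Pre-scaling transform.  log1p is the default because most raw
        variables (range size, body mass, human density) are right-skewed
        over orders of magnitude.
    proportion : bool
        If True the raw values must already lie in [0, 1]; violated bounds
        are a validation error, not silently clipped.
    """

    name: str
    role: str = "threat"
    direction: str = "direct"
    transform: str = "log1p"
    proportion: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"variable {self.name!r}: role must be one of {sorted(ROLES)}, got {self.role!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ValidationError(
                f"variable {self.name!r}: direction must be one of "
                f"{sorted(DIRECTIONS)}, got {self.direction!r}"
            )
        if self.transform not in TRANSFORMS:
            raise ValidationError(
                f"variable {self.name!r}: transform must be one of "
                f"{sorted(TRANSFORMS)}, got {self.transform!r}"
            )


class VariableTable:
    """A validated species x variable matrix with per-variable metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by species id, one column per variable.  Must contain
        no missing values (impute first, e.g. with
        :func:`impute_family_median`) and all entries must be finite.
    specs : sequence of VariableSpec
        One spec per column, in any order; names must match the columns.
    class_labels, family_labels : pandas.Series, optional
        Per-species taxonomic class / family, aligned with ``values.index``.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        specs: Sequence[VariableSpec],
        class_labels: pd.Series | None = None,
        family_labels: pd.Series | None = None,
    ) -> None:
        values = pd.DataFrame(values).astype(float)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate variable names in specs: {dupes}")
        missing = [n for n in names if n not in values.columns]
        if missing:
            raise ValidationError(f"specs name columns absent from table: {missing}")
        extra = [c for c in values.columns if c not in names]
        if extra:
            raise ValidationError(f"columns without a VariableSpec: {extra}")
        # keep column order as given by specs
        values = values[names]

        if values.shape[0] < 2:
            raise ValidationError("a variable table needs at least 2 species")
        if not any(s.role == "threat" for s in specs):
            raise ValidationError("at least one threat variable is required")
        if values.isna().any().any():
            bad = values.columns[values.isna().any()].tolist()
            raise ValidationError(
                f"missing values in columns {bad}; impute before building the table"
            )
        arr = values.to_numpy()
        if not np.isfinite(arr).all():
            bad = values.columns[~np.isfinite(arr).all(axis=0)].tolist()
            raise ValidationError(f"non-finite values in columns {bad}")
        for s in specs:
            if s.proportion:
                col = values[s.name].to_numpy()
                if (col < 0).any() or (col > 1).any():
                    offender = values.index[(col < 0) | (col > 1)][0]
                    raise ValidationError(
                        f"proportion variable {s.name!r} outside [0, 1] "
                        f"(e.g. species {offender!r})"
                    )

        def _align(lab: pd.Series | None, what: str) -> pd.Series | None:
            if lab is None:
                return None
            lab = pd.Series(lab)
            if not lab.index.equals(values.index):
                lab = lab.reindex(values.index)
            if lab.isna().any():
                bad = lab.index[lab.isna()].tolist()[:5]
                raise ValidationError(f"species without a {what} label: {bad}")
            return lab.astype(str)

        self.values = values
        self.specs = list(specs)
        self.class_labels = _align(class_labels, "class")
        self.family_labels = _align(family_labels, "family")

    # -- convenience views ------------------------------------------------
    @property
    def species_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_species(self) -> int:
        return self.values.shape[0]

    @property
    def threat_names(self) -> list[str]:
        return [s.name for s in self.specs if s.role == "threat"]

    @property
    def modifier_names(self) -> list[str]:
        return [s.name for s in self.specs if s.role == "modifier"]

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, species: Iterable) -> "VariableTable":
        idx = pd.Index(species)
        return VariableTable(
            self.values.loc[idx],
            self.specs,
            None if self.class_labels is None else self.class_labels.loc[idx],
            None if self.family_labels is None else self.family_labels.loc[idx],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<VariableTable: {self.n_species} species, "
            f"{len(self.threat_names)} threats, {len(self.modifier_names)} modifiers>"
        )


@dataclass
class WeightScheme:
    """Non-negative weights for threats (w_i) and threat-modifier interactions (z_ij).

    Only weight ratios matter: the index rescales each interaction product
    and the weighted mean, so multiplying all threat weights — or all the
    interaction weights of a single threat — by a positive constant leaves
    the scores unchanged.
    """

    threat_weights: dict[str, float]
    interaction_weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, w in self.threat_weights.items():
            if not np.isfinite(w) or w < 0:
                raise ValidationError(f"threat weight for {name!r} must be >= 0, got {w}")
        if self.threat_weights and not any(w > 0 for w in self.threat_weights.values()):
            raise ValidationError("at least one threat weight must be positive")
        for (ti, vj), z in self.interaction_weights.items():
            if not np.isfinite(z) or z < 0:
                raise ValidationError(
                    f"interaction weight for ({ti!r}, {vj!r}) must be >= 0, got {z}"
                )
        by_threat: dict[str, list[float]] = {}
        for (ti, _vj), z in self.interaction_weights.items():
            by_threat.setdefault(ti, []).append(z)
        for ti, zs in by_threat.items():
            if not any(z > 0 for z in zs):
                raise ValidationError(
                    f"threat {ti!r} has modifiers but all interaction weights are zero"
                )

    @classmethod
    def equal(cls, table: VariableTable) -> "WeightScheme":
        """Unit weights for every threat and every threat x modifier pair."""
        return cls(
            threat_weights={t: 1.0 for t in table.threat_names},
            interaction_weights={
                (t, v): 1.0 for t in table.threat_names for v in table.modifier_names
            },
        )

    def modifiers_of(self, threat: str) -> dict[str, float]:
        return {vj: z for (ti, vj), z in self.interaction_weights.items() if ti == threat}

    def replace(
        self,
        threat: str | None = None,
        modifier: str | None = None,
        value: float = 1.0,
    ) -> "WeightScheme":
        """Copy with one threat weight, or all of one modifier's z's, replaced."""
        tw = dict(self.threat_weights)
        zw = dict(self.interaction_weights)
        if threat is not None:
            if threat not in tw:
                raise KeyError(threat)
            tw[threat] = value
        if modifier is not None:
            keys = [k for k in zw if k[1] == modifier]
            if not keys:
                raise KeyError(modifier)
            for k in keys:
                zw[k] = value
        return WeightScheme(tw, zw)


def artificial_habitat_score(labels: Iterable[str]) -> pd.Series:
    """Score intolerance to artificial habitats from suitability labels.

    ``suitable`` -> 0 (the species tolerates converted habitat), ``marginal``
    -> 0.5, and ``absent``/``unassessed`` (no artificial habitat listed, or
    the species was never assessed) -> 1.

    Raises
    ------
    ValidationError
        For any label outside the recognised vocabulary.
    """
    labels = pd.Series(labels)
    cleaned = labels.astype(str).str.strip().str.lower()
    unknown = sorted(set(cleaned) - set(HABITAT_SCORES))
    if unknown:
        raise ValidationError(
            f"unrecognised habitat labels {unknown}; "
            f"expected one of {sorted(HABITAT_SCORES)}"
        )
    return cleaned.map(HABITAT_SCORES).astype(float)


def impute_family_median(
    trait_values: pd.Series, family_labels: pd.Series
) -> tuple[pd.Series, pd.DataFrame]:
    """Fill missing trait values with the median of the species' family.

    Families are imputed independently; values never cross family
    boundaries, and a family with no observed value at all is an error (a
    global median is never silently substituted).

    Returns
    -------
    filled : pandas.Series
    report : pandas.DataFrame
        One row per imputed species: ``species_id``, ``family``,
        ``imputed_value`` (the family median used).
    """
    trait_values = pd.Series(trait_values, dtype=float)
    family_labels = pd.Series(family_labels).reindex(trait_values.index)
    if family_labels.isna().any():
        bad = family_labels.index[family_labels.isna()].tolist()[:5]
        raise ValidationError(f"species without a family label: {bad}")

    missing = trait_values.isna()
    if not missing.any():
        return trait_values.copy(), pd.DataFrame(
            columns=["species_id", "family", "imputed_value"]
        )

    medians = trait_values.groupby(family_labels).median()
    gap_families = family_labels[missing].unique()
    dead = sorted(f for f in gap_families if pd.isna(medians.get(f, np.nan)))
    if dead:
        raise ValidationError(
            f"families with missing values but no observed values: {dead}; "
            "supply values or drop these species explicitly"
        )

    filled = trait_values.copy()
    filled[missing] = family_labels[missing].map(medians)
    report = pd.DataFrame(
        {
            "species_id": trait_values.index[missing],
            "family": family_labels[missing].to_numpy(),
            "imputed_value": filled[missing].to_numpy(),
        }
    ).reset_index(drop=True)
    return filled, report
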