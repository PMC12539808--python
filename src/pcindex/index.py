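"""The Proactive Conservation Index (PCI) pipeline.

The PCI is a relative, continuous conservation-priority score in [0, 1]
built from projected future threat exposures and sensitivity-modulating
traits.  For a cohort of species it proceeds:

1. **transform** — each variable x is optionally log1p-transformed
   (most raw variables are right-skewed over orders of magnitude);
2. **scale** — min-max normalisation fs(x) = (x - min x) / (max x - min x),
   so every variable lies in [0, 1] relative to the cohort;
3. **orient** — variables whose large values *reduce* priority (range size,
   brood size, protected proportion) are reflected, x -> 1 - x;
4. **interact** — for each threat i the weighted interaction product
   r_i = sum_j z_ij (t_i ⊙ v_j) couples the threat with every modifier
   trait j (⊙ is the element-wise product); a threat with no modifiers
   passes through, r_i = t_i;
5. **aggregate** — p = fs( sum_i w_i fs(r_i) / sum_i w_i ), the min-max
   scaled weighted mean of the scaled interaction products.

Because fs() absorbs any positive rescaling, only weight *ratios* matter.
Scores are relative to the scaling cohort (by default, species of the same
taxonomic class): the least-threatened species on every variable scores
exactly 0 and the most-threatened scores exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variables import ValidationError, VariableSpec, VariableTable, WeightScheme

__all__ = [
    "ConstantVariableWarning",
    "log1p_transform",
    "min_max_scale",
    "orient_variable",
    "interaction_products",
    "pci",
    "ProactiveConservationIndex",
    "PCIResults",
]


class ConstantVariableWarning(UserWarning):
    """A vector being min-max scaled was constant; it was mapped to all zeros."""


def log1p_transform(values, name: str = "", species_ids=None) -> np.ndarray:
    """Element-wise natural log of (value + 1); order-preserving.

    Values must be non-negative and finite; the error message names the
    offending species when ids are supplied.
    """
    x = np.asarray(values, dtype=float)
    bad = ~np.isfinite(x) | (x < 0)
    if bad.any():
        where = (
            list(np.asarray(species_ids)[bad][:5])
            if species_ids is not None
            else list(np.flatnonzero(bad)[:5])
        )
        raise ValidationError(
            f"log1p transform of {name or 'variable'!r} requires finite, "
            f"non-negative values; offending entries at {where}"
        )
    return np.log1p(x)


def min_max_scale(x) -> np.ndarray:
    """Min-max normalisation: (x - min) / (max - min), mapping into [0, 1].

    A constant vector is mapped to all zeros with a
    :class:`ConstantVariableWarning` (a variable that does not vary carries
    no ranking information, and zeros keep the pipeline total).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("min-max scaling needs at least 2 values")
    if not np.isfinite(x).all():
        raise ValidationError("min-max scaling requires finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn(
            "constant vector in min-max scaling; returning all zeros",
            ConstantVariableWarning,
            stacklevel=2,
        )
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def orient_variable(scaled, direction: str) -> np.ndarray:
    """Return the input for ``direct`` variables, 1 - x for ``inverted`` ones."""
    x = np.asarray(scaled, dtype=float)
    if (x < 0).any() or (x > 1).any():
        raise ValidationError("orientation applies to scaled values in [0, 1]")
    if direction == "direct":
        return x.copy()
    if direction == "inverted":
        return 1.0 - x
    raise ValidationError(f"unknown direction {direction!r}")


def interaction_products(
    T: pd.DataFrame,
    V: pd.DataFrame,
    Z: Mapping[tuple[str, str], float],
    mode: str = "multiplicative",
) -> pd.DataFrame:
    """Weighted interaction products r_i coupling threats with modifier traits.

    Column i of the result is ``r_i = sum_j z_ij (t_i ⊙ v_j)`` over the
    modifiers j that have a weight for threat i.  A threat with no modifiers
    (m = 0) passes through unchanged, ``r_i = t_i``.

    ``mode="power"`` switches to the alternative reading in which the
    interaction weight acts as an exponent, ``r_i = sum_j (t_i ⊙ v_j^z_ij)``.
    The multiplicative default is used throughout: it is the reading under
    which proportional rescaling of weights provably leaves scores unchanged.
    """
    if mode not in {"multiplicative", "power"}:
        raise ValidationError(f"unknown interaction mode {mode!r}")
    for M, what in ((T, "threat"), (V, "modifier")):
        arr = M.to_numpy(dtype=float) if M.size else np.zeros((len(M), 0))
        if arr.size and ((arr < 0).any() or (arr > 1).any()):
            raise ValidationError(f"{what} matrix entries must lie in [0, 1]")
    unknown = [
        (ti, vj) for ti, vj in Z if ti not in T.columns or vj not in V.columns
    ]
    if unknown:
        raise ValidationError(f"interaction weights refer to unknown columns: {unknown}")
    if any(z < 0 for z in Z.values()):
        raise ValidationError("interaction weights must be >= 0")

    R = {}
    for ti in T.columns:
        mods = {vj: z for (t, vj), z in Z.items() if t == ti}
        t = T[ti].to_numpy()
        if not mods:
            R[ti] = t.copy()
            continue
        r = np.zeros_like(t)
        for vj, z in mods.items():
            v = V[vj].to_numpy()
            if mode == "multiplicative":
                r += z * (t * v)
            else:
                r += t * np.power(v, z)
        R[ti] = r
    return pd.DataFrame(R, index=T.index)


def pci(R: pd.DataFrame, w: Mapping[str, float]) -> pd.Series:
    """Final aggregation: min-max scaled weighted mean of scaled products.

    Each r_i column is min-max scaled, the weighted arithmetic mean over
    threats is taken per species, and the result is min-max scaled again, so
    the cohort's extremes score exactly 0 and 1 whenever the aggregate is
    non-constant.
    """
    if R.shape[0] < 2:
        raise ValidationError("PCI aggregation needs at least 2 species")
    weights = np.array([float(w[c]) for c in R.columns])
    if (weights < 0).any():
        raise ValidationError("threat weights must be >= 0")
    total = weights.sum()
    if total <= 0:
        raise ValidationError("all threat weights are zero")
    scaled = np.column_stack([min_max_scale(R[c].to_numpy()) for c in R.columns])
    mean = scaled @ weights / total
    return pd.Series(min_max_scale(mean), index=R.index, name="pci")


@dataclass
class CohortReport:
    """Per-cohort bookkeeping emitted by a fit."""

    cohort: str
    n_species: int
    skipped: bool = False
    reason: str = ""


class PCIResults:
    """Results of a PCI fit: scores, intermediates and provenance.

    Attributes
    ----------
    scores : pandas.Series
        Final PCI in [0, 1], indexed by species id (species in skipped
        cohorts are absent).
    scaled_variables : pandas.DataFrame
        Per-variable values after transform, min-max scaling and
        orientation (the matrix clustering operates on).
    interaction_products : pandas.DataFrame
        One r_i column per threat, before the final aggregation.
    cohorts : pandas.Series
        The scaling cohort each scored species belonged to.
    weights_used : WeightScheme
    cohort_reports : list of CohortReport
        One entry per cohort, including skipped ones (< 2 species).
    """

    def __init__(
        self,
        model: "ProactiveConservationIndex",
        scores: pd.Series,
        scaled_variables: pd.DataFrame,
        interaction_products: pd.DataFrame,
        cohorts: pd.Series,
        weights_used: WeightScheme,
        cohort_reports: list[CohortReport],
    ) -> None:
        self.model = model
        self.scores = scores
        self.scaled_variables = scaled_variables
        self.interaction_products = interaction_products
        self.cohorts = cohorts
        self.weights_used = weights_used
        self.cohort_reports = cohort_reports

    @property
    def skipped_cohorts(self) -> list[str]:
        return [r.cohort for r in self.cohort_reports if r.skipped]

    def to_frame(self, intermediates: bool = False) -> pd.DataFrame:
        """Tidy scores table; optionally append r_i and scaled-variable columns."""
        out = pd.DataFrame({"cohort": self.cohorts, "pci": self.scores})
        if intermediates:
            out = out.join(self.interaction_products.add_prefix("r_"))
            out = out.join(self.scaled_variables.add_prefix("scaled_"))
        out.index.name = "species_id"
        return out

    def summary(self) -> str:
        """Human-readable account of the fit, statsmodels-style."""
        lines = ["Proactive Conservation Index", "=" * 60]
        tbl = self.model.table
        lines.append(f"Species scored:        {len(self.scores)} of {tbl.n_species}")
        lines.append(f"Cohort rule:           {self.model.cohort}")
        lines.append(
            f"Threat variables (n):  {len(tbl.threat_names)}  "
            f"Modifiers (m): {len(tbl.modifier_names)}"
        )
        lines.append("-" * 60)
        lines.append(f"{'cohort':<20}{'n':>6}{'min':>9}{'median':>9}{'max':>9}")
        for rep in self.cohort_reports:
            if rep.skipped:
                lines.append(f"{rep.cohort:<20}{rep.n_species:>6}   skipped: {rep.reason}")
                continue
            s = self.scores[self.cohorts == rep.cohort]
            lines.append(
                f"{rep.cohort:<20}{rep.n_species:>6}"
                f"{s.min():>9.3f}{s.median():>9.3f}{s.max():>9.3f}"
            )
        lines.append("-" * 60)
        lines.append("Threat weights: " + ", ".join(
            f"{k}={v:g}" for k, v in self.weights_used.threat_weights.items()
        ))
        return "\n".join(lines)

    def plot_distribution(self, by: pd.Series | None = None, ax=None):
        """Boxplots of scores, optionally grouped (e.g. by Red List category)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if by is None:
            ax.hist(self.scores, bins=30)
            ax.set_xlabel("PCI")
            ax.set_ylabel("species")
            return ax
        groups = pd.Series(by).reindex(self.scores.index)
        order = groups.dropna().unique().tolist()
        data = [self.scores[groups == g] for g in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_ylabel("PCI")
        return ax


class ProactiveConservationIndex:
    """Model object computing PCI scores for a species table.

    Parameters
    ----------
    table : VariableTable
        Validated species x variable matrix with roles / directions /
        transforms per variable.
    weights : WeightScheme, optional
        Defaults to unit weights on every threat and interaction.
    cohort : {"class", "global"} or callable
        Scaling cohort: scores are relative to species in the same cohort.
        ``"class"`` (default) scales within each taxonomic class;
        ``"global"`` pools everything.  A callable receives the table and
        returns a per-species label Series.
    interaction_mode : {"multiplicative", "power"}
        How interaction weights enter (see :func:`interaction_products`).
    """

    def __init__(
        self,
        table: VariableTable,
        weights: WeightScheme | None = None,
        cohort: str | Callable[[VariableTable], pd.Series] = "class",
        interaction_mode: str = "multiplicative",
    ) -> None:
        self.table = table
        self.weights = weights if weights is not None else WeightScheme.equal(table)
        missing_w = [t for t in table.threat_names if t not in self.weights.threat_weights]
        if missing_w:
            raise ValidationError(f"weights missing for threat variables: {missing_w}")
        if isinstance(cohort, str) and cohort not in {"class", "global"}:
            raise ValidationError("cohort must be 'class', 'global' or a callable")
        if cohort == "class" and table.class_labels is None:
            raise ValidationError(
                "cohort='class' requires class labels; pass cohort='global' otherwise"
            )
        self.cohort = cohort
        self.interaction_mode = interaction_mode

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        specs: Sequence[VariableSpec],
        species_col: str | None = None,
        class_col: str | None = None,
        family_col: str | None = None,
        **kwargs,
    ) -> "ProactiveConservationIndex":
        """Build the model from a flat DataFrame (e.g. a read CSV)."""
        df = df.copy()
        if species_col is not None:
            df = df.set_index(species_col)
        class_labels = df[class_col] if class_col else None
        family_labels = df[family_col] if family_col else None
        names = [s.name for s in specs]
        table = VariableTable(df[names], specs, class_labels, family_labels)
        return cls(table, **kwargs)

    # -- fitting ----------------------------------------------------------
    def _cohort_labels(self) -> pd.Series:
        t = self.table
        if callable(self.cohort):
            return pd.Series(self.cohort(t)).reindex(t.species_ids).astype(str)
        if self.cohort == "global":
            return pd.Series("all", index=t.species_ids)
        return t.class_labels

    def fit(self, weights: WeightScheme | None = None) -> PCIResults:
        """Run the transform -> scale -> orient -> interact -> aggregate pipeline.

        Each cohort is scaled and aggregated independently; cohorts with
        fewer than 2 species are reported and skipped.
        """
        w = weights if weights is not None else self.weights
        t = self.table
        labels = self._cohort_labels()

        scores, scaled_parts, r_parts, reports = [], [], [], []
        for cohort_name in pd.unique(labels):
            members = labels.index[labels == cohort_name]
            n = len(members)
            if n < 2:
                reports.append(
                    CohortReport(str(cohort_name), n, skipped=True, reason="< 2 species")
                )
                continue
            sub = t.values.loc[members]
            scaled = {}
            for spec in t.specs:
                x = sub[spec.name].to_numpy()
                if spec.transform == "log1p":
                    x = log1p_transform(x, spec.name, members)
                scaled[spec.name] = orient_variable(min_max_scale(x), spec.direction)
            S = pd.DataFrame(scaled, index=members)
            R = interaction_products(
                S[t.threat_names],
                S[t.modifier_names],
                w.interaction_weights,
                mode=self.interaction_mode,
            )
            p = pci(R, w.threat_weights)
            scores.append(p)
            scaled_parts.append(S)
            r_parts.append(R)
            reports.append(CohortReport(str(cohort_name), n))

        if not scores:
            raise ValidationError("no cohort had at least 2 species")
        all_scores = pd.concat(scores)
        order = t.species_ids[t.species_ids.isin(all_scores.index)]
        return PCIResults(
            model=self,
            scores=all_scores.loc[order].rename("pci"),
            scaled_variables=pd.concat(scaled_parts).loc[order],
            interaction_products=pd.concat(r_parts).loc[order],
            cohorts=labels.loc[order].rename("cohort"),
            weights_used=w,
            cohort_reports=reports,
        )

    def fit_weights(self, reference_ranks: pd.Series, **kwargs):
        """Optimise threat weights so scores rank-match an external reference.

        Thin delegate to :func:`pcindex.weights_opt.optimize_weights`.
        """
        from .weights_opt import optimize_weights

        return optimize_weights(self, reference_ranks, **kwargs)
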