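"""Agreement between PCI scores and the IUCN Red List.

The Red List is an ordinal extinction-risk scale; the index is a continuous
future-threat priority.  This module quantifies how far the two agree:
tie-corrected Spearman correlation against the ordinal encoding
(LC=1 .. CR=5; DD and NE carry no rank), per-category score distributions,
a family-level quartile cross-tabulation, and an ecoregion-level binomial
GLM of the proportion of threatened species (VU/EN/CR) on mean PCI, whose
residuals map where the index flags more (or less) future priority than
current assessments suggest.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .variables import ValidationError

ORDINAL_MAP = {"LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5}
EXCLUDED_CATEGORIES = frozenset({"DD", "NE"})
THREATENED = frozenset({"VU", "EN", "CR"})
#: Red List criteria based solely on projected future decline (A3) or a
#: quantitative extinction-probability analysis (E).
FUTURE_CRITERIA = frozenset({"A3", "E"})


def ordinal_encode_redlist(labels) -> pd.Series:
    """Map LC..CR to ranks 1..5; DD and NE become NaN (excluded, not ranked)."""
    labels = pd.Series(labels).astype(str).str.strip().str.upper()
    unknown = sorted(set(labels) - set(ORDINAL_MAP) - EXCLUDED_CATEGORIES)
    if unknown:
        raise ValidationError(
            f"unknown Red List categories {unknown}; "
            f"expected {sorted(ORDINAL_MAP)} or {sorted(EXCLUDED_CATEGORIES)}"
        )
    return labels.map(ORDINAL_MAP).astype(float)


def decode_ordinal(ranks) -> pd.Series:
    """Inverse of :func:`ordinal_encode_redlist` for ranks 1..5."""
    inv = {v: k for k, v in ORDINAL_MAP.items()}
    ranks = pd.Series(ranks)
    bad = sorted(set(ranks.dropna()) - set(inv))
    if bad:
        raise ValidationError(f"ranks outside 1..5: {bad}")
    return ranks.map(inv)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p by full enumeration (n <= 10).

    Enumerates every permutation of one argument's average ranks; with ties
    the rank multiset is fixed, so the statistic reduces to a dot product
    with the other argument's centred ranks.
    """
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    rx_c = rx - rx.mean()
    n = len(rx)
    denom = np.sqrt((rx_c**2).sum() * ((ry - ry.mean()) ** 2).sum())
    if denom == 0:
        raise ValidationError("constant vector: Spearman correlation undefined")
    hits = 0
    total = 0
    tol = 1e-12

    def count(chunk: list[tuple]) -> int:
        rhos = (np.array(chunk) - ry.mean()) @ rx_c / denom
        return int((np.abs(rhos) >= abs(rho_obs) - tol).sum())

    chunk: list[tuple] = []
    for perm in itertools.permutations(ry):
        chunk.append(perm)
        if len(chunk) == 200_000:
            hits += count(chunk)
            total += len(chunk)
            chunk = []
    if chunk:
        hits += count(chunk)
        total += len(chunk)
    return hits / total


def spearman_rho(x, y) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation with a p-value.

    Average ranks are used for ties.  The p-value uses the t-approximation
    for n > 10 and an exact full-enumeration permutation test for n <= 10,
    where the approximation is unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("Spearman correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant vector: Spearman correlation undefined")
    rho, p = st.spearmanr(x, y)
    if n <= 10:
        p = _spearman_exact_p(x, y, rho)
    return SpearmanResult(float(rho), float(p), n)


def category_distribution(scores: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Per-category summary of PCI scores (median, mean, SD, SE, n).

    All categories present are summarised, including DD and NE — the index
    is defined for unassessed species, which is part of its point.  SD uses
    the n-1 denominator and is reported missing for singleton categories.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels).reindex(scores.index)
    if labels.isna().any():
        raise ValidationError("every scored species needs a category label")
    if scores.empty:
        raise ValidationError("no species to summarise")
    rows = []
    for cat, vals in scores.groupby(labels.astype(str)):
        n = len(vals)
        sd = vals.std(ddof=1) if n > 1 else np.nan
        rows.append(
            {
                "category": cat,
                "n": n,
                "median": vals.median(),
                "mean": vals.mean(),
                "sd": sd,
                "se": sd / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    order = {c: i for i, c in enumerate(["LC", "NT", "VU", "EN", "CR", "DD", "NE"])}
    rows.sort(key=lambda r: order.get(r["category"], 99))
    return pd.DataFrame(rows).set_index("category")


def _parse_criteria(value) -> set[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    if isinstance(value, str):
        return {c.strip() for c in value.replace(",", ";").split(";") if c.strip()}
    return set(value)


def criteria_subset(labels: pd.DataFrame) -> pd.Series:
    """Mask selecting the future-criteria comparison subset.

    Keeps threatened species (VU/EN/CR) whose assessment criteria include
    A3 or E — the criteria based solely on future threats — together with
    all non-threatened species (LC and NT).  Threatened species with no
    criteria recorded are dropped from the threatened side.  DD/NE are
    excluded.

    Parameters
    ----------
    labels : DataFrame with columns ``category`` and ``criteria``
        (semicolon-separated string or an iterable of codes).
    """
    cats = labels["category"].astype(str).str.upper()
    crits = labels["criteria"] if "criteria" in labels else pd.Series(index=labels.index)
    mask = pd.Series(False, index=labels.index)
    mask[cats.isin(["LC", "NT"])] = True
    threatened = cats.isin(THREATENED)
    has_future = crits.reindex(labels.index).map(
        lambda v: bool(_parse_criteria(v) & FUTURE_CRITERIA)
    )
    mask[threatened & has_future] = True
    return mask


def proportion_threatened(labels: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group proportion of threatened species among assessed species.

    Threatened means VU, EN or CR.  DD and NE species are removed from both
    numerator and denominator (they cannot be classified either way); the
    counts are retained for GLM weighting.  Groups left empty after the
    removal are reported with missing statistics.
    """
    labels = pd.Series(labels).astype(str).str.upper()
    groups = pd.Series(groups).reindex(labels.index)
    rows = []
    for g, cats in labels.groupby(groups.astype(str)):
        assessed = cats[~cats.isin(EXCLUDED_CATEGORIES)]
        k = int(assessed.isin(THREATENED).sum())
        n = int(len(assessed))
        rows.append(
            {
                "group": g,
                "threatened": k,
                "assessed": n,
                "proportion": k / n if n else np.nan,
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    empty = out.index[out["assessed"] == 0].tolist()
    if empty:
        warnings.warn(f"groups with no assessed species: {empty}", stacklevel=2)
    return out


def signed_log(residuals, scale: float = 1.0) -> np.ndarray:
    """Sign-preserving log transform sign(r) * ln(1 + |r| / s).

    Odd, monotone, and zero-preserving; used to stretch small GLM response
    residuals for mapping without discarding their sign.
    """
    r = np.asarray(residuals, dtype=float)
    if not np.isfinite(r).all():
        raise ValidationError("residuals must be finite")
    if scale <= 0:
        raise ValidationError("scale must be positive")
    return np.sign(r) * np.log1p(np.abs(r) / scale)


class ThreatProportionGLMResults:
    """Results of the ecoregion-level binomial GLM (statsmodels wrapper).

    Exposes the slope of mean PCI on the log-odds of being threatened, its
    standard error / z / p, fitted per-group proportions and response-scale
    residuals (observed - fitted proportion).
    """

    def __init__(self, sm_results, observed_proportion: pd.Series, weighted: bool) -> None:
        self._sm = sm_results
        self.weighted = weighted
        self.coefficient = float(sm_results.params.iloc[1])
        self.std_error = float(sm_results.bse.iloc[1])
        self.z_value = float(sm_results.tvalues.iloc[1])
        self.p_value = float(sm_results.pvalues.iloc[1])
        self.intercept = float(sm_results.params.iloc[0])
        self.fitted = pd.Series(
            np.asarray(sm_results.mu), index=observed_proportion.index, name="fitted"
        )
        self.residuals = (observed_proportion - self.fitted).rename("residual")

    def signed_log_residuals(self, scale: float = 1.0) -> pd.Series:
        return pd.Series(
            signed_log(self.residuals, scale), index=self.residuals.index,
            name="signed_log_residual",
        )

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self._sm.params.to_numpy(),
                "std_error": self._sm.bse.to_numpy(),
                "z_value": self._sm.tvalues.to_numpy(),
                "p_value": self._sm.pvalues.to_numpy(),
            },
            index=["intercept", "mean_pci"],
        )

    def summary(self) -> str:
        note = "" if self.weighted else (
            "\nNote: fitted on proportions without counts (quasi-binomial); "
            "standard errors are not comparable to count-weighted fits."
        )
        return str(self._sm.summary()) + note


class ThreatProportionGLM:
    """Binomial-logit GLM of per-group threatened proportion on mean PCI.

    logit(p_g) = b0 + b1 * meanPCI_g, fitted by IRLS on binomial counts.
    A positive b1 means regions the index prioritises also hold more
    currently threatened species; the residual map shows where the two
    prioritisations diverge.
    """

    def __init__(self, threatened, totals, mean_pci) -> None:
        threatened = pd.Series(threatened).astype(float)
        self.totals = pd.Series(totals).astype(float).reindex(threatened.index)
        self.mean_pci = pd.Series(mean_pci).astype(float).reindex(threatened.index)
        self.threatened = threatened
        if len(threatened) < 3:
            raise ValidationError("the GLM needs at least 3 groups")
        if (self.totals < 1).any():
            raise ValidationError("every group needs at least one assessed species")
        if (threatened > self.totals).any():
            raise ValidationError("threatened count exceeds total in some group")
        self._weighted = True

    @classmethod
    def from_proportions(cls, proportions, mean_pci) -> "ThreatProportionGLM":
        """Build from proportions only (no counts): unweighted quasi-binomial.

        Coefficient point estimates are comparable to the weighted fit only
        if group sizes are similar; standard errors are flagged in the
        summary as not count-weighted.
        """
        proportions = pd.Series(proportions).astype(float)
        obj = cls.__new__(cls)
        obj.threatened = proportions
        obj.totals = pd.Series(1.0, index=proportions.index)
        obj.mean_pci = pd.Series(mean_pci).astype(float).reindex(proportions.index)
        if len(proportions) < 3:
            raise ValidationError("the GLM needs at least 3 groups")
        obj._weighted = False
        return obj

    def fit(self, maxiter: int = 100) -> ThreatProportionGLMResults:
        exog = sm.add_constant(self.mean_pci.rename("mean_pci"))
        if self._weighted:
            endog = np.column_stack(
                [self.threatened, self.totals - self.threatened]
            )
        else:
            endog = self.threatened
        model = sm.GLM(endog, exog, family=sm.families.Binomial())
        from statsmodels.tools.sm_exceptions import PerfectSeparationError

        try:
            with warnings.catch_warnings():
                warnings.filterwarnings(
                    "error", category=getattr(
                        sm.tools.sm_exceptions, "PerfectSeparationWarning", Warning
                    )
                )
                res = model.fit(
                    maxiter=maxiter,
                    scale=None if self._weighted else "X2",
                )
        except PerfectSeparationError as err:
            raise ValidationError(
                "complete separation: the threatened proportion is perfectly "
                "predicted by mean PCI; coefficients are unbounded"
            ) from err
        except Warning as werr:  # promoted separation warning
            raise ValidationError(
                f"separation detected during IRLS: {werr}"
            ) from werr
        if not getattr(res, "converged", True):
            trace = res.fit_history.get("deviance", [])
            raise ValidationError(
                f"IRLS did not converge in {maxiter} iterations; "
                f"deviance trace: {list(np.round(trace, 4))}"
            )
        observed = self.threatened / self.totals if self._weighted else self.threatened
        return ThreatProportionGLMResults(res, observed, self._weighted)


def _quartile_bins(values: pd.Series) -> pd.Series:
    """Quartile 1-4 per value: linear-interpolation sample quantiles, ties
    resolved by assigning every tied value the bin of its average rank's
    quantile position (identical values always share a quartile)."""
    v = values.to_numpy(dtype=float)
    qs = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    # average ranks make tied values identical before binning
    bins = np.searchsorted(qs, v, side="left") + 1
    # any value exactly equal to a cut falls below it (side="left"), so
    # ties at a boundary land together
    return pd.Series(bins, index=values.index)


@dataclass
class QuartileCrosstab:
    """Family-level agreement between mean PCI and proportion threatened."""

    table: pd.DataFrame  # per family: both quartiles, stratum, n_species
    agreement: float  # fraction of families in the same quartile on both
    discordant: pd.DataFrame  # (Q4, Q1) / (Q1, Q4) families

    def discordant_small_family_fraction(self, max_species: int = 5) -> float:
        """Fraction of maximally discordant families with <= max_species species."""
        if self.discordant.empty:
            return np.nan
        return float((self.discordant["n_species"] <= max_species).mean())


def quartile_crosstab(
    family_mean_pci: pd.Series,
    family_prop_threatened: pd.Series,
    strata: pd.Series | None = None,
    species_counts: pd.Series | None = None,
) -> QuartileCrosstab:
    """Cross-tabulate family quartiles of mean PCI vs proportion threatened.

    Each family receives a quartile (1-4) for each measure within its
    stratum (pass per-class strata to reproduce within-class quartiles, or
    None to pool).  Reports the fraction of families whose two quartiles
    match and lists the maximally discordant families — top quartile on one
    measure, bottom on the other — the taxa one method prioritises and the
    other ignores.  Strata with fewer than 4 families are reported and
    skipped.
    """
    pci_vals = pd.Series(family_mean_pci).astype(float)
    prop = pd.Series(family_prop_threatened).astype(float).reindex(pci_vals.index)
    if prop.isna().any():
        raise ValidationError("families missing a threatened proportion")
    strata = (
        pd.Series("all", index=pci_vals.index)
        if strata is None
        else pd.Series(strata).reindex(pci_vals.index).astype(str)
    )
    counts = (
        pd.Series(np.nan, index=pci_vals.index)
        if species_counts is None
        else pd.Series(species_counts).reindex(pci_vals.index)
    )

    frames = []
    for name, idx in pci_vals.groupby(strata).groups.items():
        if len(idx) < 4:
            warnings.warn(
                f"stratum {name!r} has {len(idx)} < 4 families; skipped", stacklevel=2
            )
            continue
        frames.append(
            pd.DataFrame(
                {
                    "stratum": name,
                    "pci_quartile": _quartile_bins(pci_vals.loc[idx]),
                    "threat_quartile": _quartile_bins(prop.loc[idx]),
                    "n_species": counts.loc[idx],
                }
            )
        )
    if not frames:
        raise ValidationError("no stratum had at least 4 families")
    table = pd.concat(frames)
    table.index.name = "family"
    agreement = float((table["pci_quartile"] == table["threat_quartile"]).mean())
    disc_mask = (
        ((table["pci_quartile"] == 4) & (table["threat_quartile"] == 1))
        | ((table["pci_quartile"] == 1) & (table["threat_quartile"] == 4))
    )
    return QuartileCrosstab(
        table=table, agreement=agreement, discordant=table[disc_mask].copy()
    )
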