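"""Aggregation of species scores over taxonomy, space and phylogeny.

Family means summarise priority per clade; ecoregion means and sums pool
every species whose range overlaps a region (a species overlapping k
regions contributes fully to all k — there is no area splitting); and tree
node averaging paints mean priority onto internal nodes of a phylogeny,
each node taking the mean of its descendant *tips*.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .variables import ValidationError

__all__ = [
    "family_mean_pci",
    "region_aggregate",
    "membership_matrix",
    "tree_node_averages",
    "read_tree",
    "write_annotated_newick",
]


def family_mean_pci(scores: pd.Series, family_labels: pd.Series) -> pd.DataFrame:
    """Arithmetic mean score per family, with species counts."""
    scores = pd.Series(scores).astype(float)
    fams = pd.Series(family_labels).reindex(scores.index)
    if fams.isna().any():
        bad = fams.index[fams.isna()].tolist()[:5]
        raise ValidationError(f"species without a family label: {bad}")
    grouped = scores.groupby(fams.astype(str))
    return pd.DataFrame({"mean_pci": grouped.mean(), "n": grouped.size()})


def membership_matrix(long: pd.DataFrame) -> pd.DataFrame:
    """Species x region boolean incidence from a long (species_id, region_id) table."""
    if not {"species_id", "region_id"} <= set(long.columns):
        raise ValidationError("membership table needs species_id and region_id columns")
    return pd.crosstab(long["species_id"], long["region_id"]).astype(bool)


def region_aggregate(scores: pd.Series, membership: pd.DataFrame) -> pd.DataFrame:
    """Mean and sum of scores over the species overlapping each region.

    ``membership`` is a species x region boolean matrix (see
    :func:`membership_matrix`).  Regions with no members get missing
    statistics and a warning; species scored but absent from every region
    are reported the same way.
    """
    scores = pd.Series(scores).astype(float)
    M = membership.astype(bool)
    missing_species = scores.index.difference(M.index)
    if len(missing_species):
        warnings.warn(
            f"{len(missing_species)} scored species absent from the membership "
            f"table (e.g. {list(missing_species[:3])})",
            stacklevel=2,
        )
    M = M.reindex(index=scores.index, fill_value=False)
    orphan = scores.index[~M.any(axis=1)]
    if len(orphan):
        warnings.warn(
            f"{len(orphan)} species overlap no region (e.g. {list(orphan[:3])})",
            stacklevel=2,
        )
    rows = []
    s = scores.to_numpy()
    for region in M.columns:
        mask = M[region].to_numpy()
        n = int(mask.sum())
        rows.append(
            {
                "region": region,
                "n": n,
                "mean_pci": s[mask].mean() if n else np.nan,
                "sum_pci": s[mask].sum() if n else np.nan,
            }
        )
    empty = [r["region"] for r in rows if r["n"] == 0]
    if empty:
        warnings.warn(f"regions with zero members: {empty}", stacklevel=2)
    return pd.DataFrame(rows).set_index("region")


def read_tree(path_or_string: str, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree; tip labels are expected to be species ids."""
    try:
        if "(" in path_or_string:
            return dendropy.Tree.get(data=path_or_string, schema=schema)
        return dendropy.Tree.get(path=path_or_string, schema=schema)
    except Exception as err:  # dendropy raises assorted parse errors
        raise ValidationError(f"could not parse tree: {err}") from err


def tree_node_averages(
    tree: dendropy.Tree, tip_values: Mapping[str, float] | pd.Series,
    attr: str = "mean_pci",
) -> dict:
    """Assign every node the mean value of its descendant tips.

    Tips keep their own value; internal nodes average over descendant
    *tips* (not child-node values — the two differ on unbalanced trees and
    only the tip average is independent of the internal topology).  The
    value is stored on each node as attribute ``attr`` and also returned as
    a dict keyed by taxon label for tips and by node object for internal
    nodes.

    Raises
    ------
    ValidationError
        If any tip lacks a value (all missing tips are listed).
    """
    vals = dict(pd.Series(tip_values))
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValidationError("tree must have at least 2 tips")
    missing = sorted(
        (lf.taxon.label if lf.taxon is not None else "<unlabelled tip>")
        for lf in leaves
        if lf.taxon is None or lf.taxon.label not in vals
    )
    if missing:
        raise ValidationError(f"tips without a value: {missing}")

    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            total, n = float(vals[node.taxon.label]), 1
        else:
            total = sum(ch._pci_sum for ch in node.child_nodes())
            n = sum(ch._pci_n for ch in node.child_nodes())
        node._pci_sum, node._pci_n = total, n
        value = total / n
        setattr(node, attr, value)
        node.annotations.add_new(attr, round(value, 10))
        key = node.taxon.label if node.is_leaf() else node
        out[key] = value
    return out


def write_annotated_newick(tree: dendropy.Tree, path: str) -> None:
    """Write the tree with node annotations (e.g. mean scores) as newick comments."""
    tree.write(
        path=path,
        schema="newick",
        suppress_annotations=False,
        annotations_as_nhx=True,
    )
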