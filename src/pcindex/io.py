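"""Reading species tables and configuration files, writing tidy outputs.

The table format is delimited text (CSV or TSV, sniffed from the
extension) with a header row and empty fields for missing values.  The
variable metadata and weights live in a YAML config:

.. code-block:: yaml

    species_col: species_id
    class_col: class
    family_col: family
    variables:
      - {name: climate_exposure, role: threat, direction: direct,
         transform: log1p, proportion: true}
      - {name: body_mass_g, role: modifier}
    weights:
      threats: {climate_exposure: 1.0}
      interactions: {"climate_exposure:body_mass_g": 1.0}

Omitted weights default to 1 for every threat and every threat x modifier
pair; interaction keys are ``"threat:modifier"`` strings.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .variables import (
    ValidationError,
    VariableSpec,
    VariableTable,
    WeightScheme,
    impute_family_median,
)

__all__ = ["load_config", "specs_from_config", "weights_from_config",
           "read_species_table", "write_weights_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "variables" not in cfg:
        raise ValidationError(f"config {path} must be a mapping with a 'variables' list")
    return cfg


def specs_from_config(cfg: dict) -> list[VariableSpec]:
    specs = []
    for entry in cfg["variables"]:
        if isinstance(entry, str):
            entry = {"name": entry}
        specs.append(
            VariableSpec(
                name=entry["name"],
                role=entry.get("role", "threat"),
                direction=entry.get("direction", "direct"),
                transform=entry.get("transform", "log1p"),
                proportion=bool(entry.get("proportion", False)),
            )
        )
    return specs


def weights_from_config(cfg: dict, specs: list[VariableSpec]) -> WeightScheme:
    threats = [s.name for s in specs if s.role == "threat"]
    modifiers = [s.name for s in specs if s.role == "modifier"]
    wcfg = cfg.get("weights") or {}
    tw = {t: 1.0 for t in threats}
    tw.update({k: float(v) for k, v in (wcfg.get("threats") or {}).items()})
    zw = {(t, v): 1.0 for t in threats for v in modifiers}
    for key, z in (wcfg.get("interactions") or {}).items():
        if ":" not in key:
            raise ValidationError(
                f"interaction weight key {key!r} must be 'threat:modifier'"
            )
        ti, vj = (part.strip() for part in key.split(":", 1))
        zw[(ti, vj)] = float(z)
    unknown = [t for t in tw if t not in threats]
    if unknown:
        raise ValidationError(f"weights for unknown threat variables: {unknown}")
    return WeightScheme(threat_weights=tw, interaction_weights=zw)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def read_species_table(
    table_path: str | Path, cfg: dict, impute: bool = True
) -> tuple[VariableTable, pd.DataFrame]:
    """Read a delimited species table under a config.

    Missing trait values (empty fields) are filled by family medians when
    ``impute`` is on and a family column is configured; the imputation
    report is returned alongside.  Any missingness still present
    afterwards is a hard error — species are never silently dropped.
    """
    df = _read_delimited(table_path)
    species_col = cfg.get("species_col", "species_id")
    if species_col not in df.columns:
        raise ValidationError(f"table lacks the species column {species_col!r}")
    df = df.set_index(species_col)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate species ids: {dupes}")

    specs = specs_from_config(cfg)
    class_col = cfg.get("class_col")
    family_col = cfg.get("family_col")
    families = df[family_col] if family_col and family_col in df.columns else None

    reports = []
    if impute and families is not None:
        for s in specs:
            if df[s.name].isna().any():
                df[s.name], rep = impute_family_median(df[s.name], families)
                rep.insert(0, "variable", s.name)
                reports.append(rep)
    report = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(columns=["variable", "species_id", "family", "imputed_value"])
    )

    table = VariableTable(
        df[[s.name for s in specs]],
        specs,
        class_labels=df[class_col] if class_col and class_col in df.columns else None,
        family_labels=families,
    )
    return table, report


def write_weights_config(weights: WeightScheme, path: str | Path) -> None:
    """Write a weight scheme in the same YAML dialect ``pci compute`` reads."""
    payload = {
        "weights": {
            "threats": {k: float(v) for k, v in weights.threat_weights.items()},
            "interactions": {
                f"{t}:{v}": float(z)
                for (t, v), z in weights.interaction_weights.items()
            },
        }
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
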