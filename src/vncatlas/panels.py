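"""Marker-panel configuration.

A :class:`MarkerPanel` maps gene symbols to role tags drawn from a closed
vocabulary.  The packaged default configuration transcribes the marker tables
used by the annotation layer: neuronal / glial identity markers, the five
fast-acting-neurotransmitter (FAN) markers, the four Hox genes, the 28-gene
neuropeptide precursor list, monoaminergic and glial subtype biomarkers, and
salivary-gland / sperm contaminant signatures.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError, VocabularyError

__all__ = [
    "MarkerPanel",
    "ROLE_VOCABULARY",
    "load_marker_panels",
    "default_panels",
    "panels_by_name",
    "load_hemilineage_panel",
    "default_hemilineage_panel",
]

ROLE_VOCABULARY = frozenset(
    {
        "neuronal",
        "glial",
        "FAN:ACh",
        "FAN:Glu",
        "FAN:GABA",
        "hox",
        "neuropeptide",
        "monoamine:pan",
        "monoamine:DA",
        "monoamine:5-HT",
        "monoamine:HA",
        "monoamine:OA/TA",
        "glia:astrocyte",
        "glia:surface",
        "glia:cortex",
        "glia:ensheathing",
        "contaminant:salivary",
        "contaminant:sperm",
    }
)


@dataclass
class MarkerPanel:
    name: str
    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise FormatError(f"panel {self.name!r} is empty")
        for gene, role in self.entries.items():
            if not gene:
                raise FormatError(f"panel {self.name!r} has an empty gene symbol")
            if role not in ROLE_VOCABULARY:
                raise VocabularyError(
                    f"panel {self.name!r}, gene {gene!r}: unknown role {role!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.entries)

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.entries.items() if r == role]


def _panels_from_rows(rows: pd.DataFrame) -> list[MarkerPanel]:
    if rows.empty:
        raise FormatError("marker-panel table has no rows")
    dup = rows.duplicated(subset=["gene", "panel"])
    if dup.any():
        bad = rows[dup].iloc[0]
        raise FormatError(f"duplicate (gene, panel) row: ({bad['gene']}, {bad['panel']})")
    panels = []
    for name, grp in rows.groupby("panel", sort=False):
        panels.append(MarkerPanel(name, dict(zip(grp["gene"], grp["role"]))))
    return panels


def load_marker_panels(path: str | Path) -> list[MarkerPanel]:
    """Load marker panels from a TSV (gene, panel, role) or YAML file.

    YAML layout: ``{panel_name: {gene: role, ...}, ...}``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"panel config {path} does not exist")
    if path.suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not payload:
            raise FormatError(f"{path} contains no panels")
        rows = pd.DataFrame(
            [
                {"gene": g, "panel": p, "role": r}
                for p, entries in payload.items()
                for g, r in (entries or {}).items()
            ]
        )
        if rows.empty or set(payload) - set(rows.get("panel", [])):
            raise FormatError(f"{path} contains an empty panel")
        return _panels_from_rows(rows)
    rows = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    expected = {"gene", "panel", "role"}
    if not expected.issubset(rows.columns):
        raise FormatError(f"{path} must have columns {sorted(expected)}")
    return _panels_from_rows(rows)


def default_panels() -> list[MarkerPanel]:
    """The packaged marker-panel configuration."""
    ref = importlib.resources.files("vncatlas") / "data" / "marker_panels.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_marker_panels(path)


def panels_by_name(panels: list[MarkerPanel] | None = None) -> dict[str, MarkerPanel]:
    if panels is None:
        panels = default_panels()
    return {p.name: p for p in panels}


def load_hemilineage_panel(path: str | Path) -> pd.DataFrame:
    """Hemilineage marker table: one row per hemilineage with its required
    FAN identity and positive marker genes (comma-separated in the file)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"hemilineage", "fan", "markers"}
    if not expected.issubset(df.columns):
        raise FormatError(f"{path} must have columns {sorted(expected)}")
    if df.empty:
        raise FormatError(f"{path} contains no hemilineages")
    df = df.set_index("hemilineage")
    df["markers"] = df["markers"].map(lambda s: [m.strip() for m in s.split(",") if m.strip()])
    if (df["markers"].map(len) == 0).any():
        raise FormatError("hemilineage with no markers")
    return df


def default_hemilineage_panel() -> pd.DataFrame:
    ref = importlib.resources.files("vncatlas") / "data" / "hemilineage_panel.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_hemilineage_panel(path)
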