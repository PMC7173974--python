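"""End-to-end pipeline orchestration with a single config, stage outputs as
TSV tables, and a summary.json of headline aggregates.  A thin layer over
:class:`vncatlas.model.VNCAtlas`."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .model import AtlasConfig, AtlasResults, VNCAtlas
from .panels import load_hemilineage_panel, load_marker_panels
from .simulate import CompositionSpec, default_composition, generate_atlas

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("vncatlas")


@dataclass
class PipelineConfig:
    """Validated end-to-end configuration.

    ``input_10x`` points at an MTX triplet directory; alternatively
    ``simulate=True`` generates the packaged default fixture (or the
    composition in ``composition_yaml``).  The resolved config is serialised
    alongside the outputs for provenance.
    """

    out_dir: str = "atlas_out"
    input_10x: str | None = None
    simulate: bool = False
    composition_yaml: str | None = None
    panel_file: str | None = None
    hemilineage_file: str | None = None
    seed: int = 42
    atlas: AtlasConfig = field(default_factory=AtlasConfig)

    def validate(self) -> None:
        if not self.simulate and self.input_10x is None:
            raise ValidationError("either simulate=True or input_10x must be given")
        self.atlas.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        atlas = AtlasConfig(**payload.pop("atlas", {}))
        return cls(atlas=atlas, **payload)


def run_pipeline(config: PipelineConfig) -> AtlasResults:
    """Run every enabled stage, writing stage tables + summary.json to
    ``config.out_dir``.  Deterministic given the seed.  A stage failure
    aborts with the stage name; tables written so far are kept."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    stage = "input"
    try:
        truth = None
        if config.simulate:
            comp = (
                CompositionSpec.from_yaml(config.composition_yaml)
                if config.composition_yaml
                else default_composition(seed=config.seed)
            )
            comp.seed = config.seed
            counts, truth = generate_atlas(comp)
            truth.cells.to_csv(out / "ground_truth.tsv", sep="\t")
        else:
            from .io import read_counts_10x

            counts = read_counts_10x(config.input_10x)
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)

        stage = "fit"
        panels = load_marker_panels(config.panel_file) if config.panel_file else None
        hemi = load_hemilineage_panel(config.hemilineage_file) if config.hemilineage_file else None
        config.atlas.seed = config.seed
        model = VNCAtlas(counts, panels=panels, hemilineage_panel=hemi, config=config.atlas)
        res = model.fit()
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)

        stage = "write"
        _write_outputs(res, out, config)
        log.info("pipeline done (%.1fs)", time.time() - t0)
        return res
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def _write_outputs(res: AtlasResults, out: Path, config: PipelineConfig) -> None:
    res.cell_qc.to_csv(out / "qc_report.tsv", sep="\t")
    res.cell_table.to_csv(out / "cell_annotations.tsv", sep="\t")
    pd.DataFrame(
        {"barcode": res.adata.obs_names, "cluster": res.labels}
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    cluster_tab = pd.DataFrame(
        {
            "class": res.classes,
            "fan": res.cluster_fan,
            "n_cells": pd.Series(res.labels).value_counts().sort_index(),
        }
    )
    if res.hemilineages is not None:
        cluster_tab["hemilineage"] = res.hemilineages["hemilineage"]
        cluster_tab["hemilineage_score"] = res.hemilineages["score"]
    cluster_tab.to_csv(out / "cluster_annotations.tsv", sep="\t")

    if res.markers is not None:
        res.markers.to_csv(out / "markers.tsv", sep="\t", index=False)
    if res.census is not None:
        res.census.to_csv(out / "np_census.tsv", sep="\t", index=False)
    if res.percentiles is not None:
        res.percentiles.to_csv(out / "np_summary.tsv", sep="\t")
    if res.background_split is not None:
        pd.DataFrame([vars(res.background_split)]).to_csv(
            out / "background_split.tsv", sep="\t", index=False
        )
    if res.correlations is not None:
        res.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    if res.coexpression is not None:
        res.coexpression["pairs"].to_csv(out / "coexpression_report.tsv", sep="\t")
    for name, run in res.subtypes.items():
        pd.DataFrame(
            {
                "barcode": run.barcodes,
                "subcluster": run.labels,
                "subtype": [run.subtype_labels.get(c) for c in run.labels],
            }
        ).to_csv(out / f"subclusters_{name}.tsv", sep="\t", index=False)

    summary = res.summary_dict()
    summary["seed"] = config.seed
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    cfg = asdict(config)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
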