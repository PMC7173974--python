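"""The atlas model: a statsmodels-style estimator object.

:class:`VNCAtlas` wraps a raw UMI count matrix plus marker-panel
configuration; :meth:`VNCAtlas.fit` runs the full analysis -- QC filtering,
log normalization, covariate-regressed scaling, variable-gene selection,
between-sex CCA, SNN/Louvain clustering, marker detection, rule-based
annotation (class, FAN, hemilineage, neuromere), sub-clustering, the
neuropeptide census and co-expression tables -- and returns an
:class:`AtlasResults` carrying every stage table, headline aggregates and a
``summary()`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import annotate as ann
from . import census as census_mod
from . import coexpr, qc as qc_mod
from .errors import ValidationError
from .markers import cluster_average_expression, find_markers_nb
from .panels import (
    MarkerPanel,
    default_hemilineage_panel,
    default_panels,
)
from .preprocess import (
    Clustering,
    batch_mixing_metric,
    cca_reduce,
    cluster_louvain,
    log_normalize,
    regress_and_scale,
    select_variable_genes,
)
from .subtype import PRESETS, label_by_biomarkers, subcluster_cells

__all__ = ["AtlasConfig", "VNCAtlas", "AtlasResults"]


@dataclass
class AtlasConfig:
    """Tunable parameters of the atlas fit (defaults follow the published
    analysis): QC gates, reduction dimensionality, clustering resolution,
    marker-test gates and stage toggles."""

    min_umi: float = 1200.0
    max_umi: float | None = 10000.0
    min_genes: int = 200
    max_mito: float = 0.15
    min_cells_per_gene: int = 3
    auto_min_umi: bool = False
    dims: int = 45
    resolution: float = 12.0
    k_neighbors: int = 30
    logfc_min: float = 0.5
    alpha: float = 0.05
    seed: int = 42
    # stage toggles
    do_markers: bool = True
    marker_genes: str | list = "contaminant"  # "all" | "contaminant" | gene list
    do_subtypes: bool = True
    do_census: bool = True
    do_coexpression: bool = True
    do_hemilineages: bool = True
    background_gene: str = "Orcokinin"

    def validate(self) -> None:
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")
        if self.dims <= 0:
            raise ValidationError("dims must be positive")
        if self.min_umi < 0 or (self.max_umi is not None and self.max_umi <= self.min_umi):
            raise ValidationError("invalid nUMI bounds")
        if not (0 <= self.max_mito <= 1):
            raise ValidationError("max_mito must be in [0, 1]")


class VNCAtlas:
    """Model object built from a raw counts AnnData (cells x genes, with
    ``replicate`` and optionally ``sex`` in ``.obs``)."""

    def __init__(
        self,
        counts: ad.AnnData,
        panels: list[MarkerPanel] | None = None,
        hemilineage_panel: pd.DataFrame | None = None,
        config: AtlasConfig | None = None,
    ):
        self.counts = counts
        self.panels = {p.name: p for p in (panels or default_panels())}
        self.hemilineage_panel = (
            hemilineage_panel if hemilineage_panel is not None else default_hemilineage_panel()
        )
        self.config = config or AtlasConfig()
        self.config.validate()

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_10x(cls, path, **kwargs) -> "VNCAtlas":
        from .io import read_counts_10x

        return cls(read_counts_10x(path), **kwargs)

    @classmethod
    def from_simulation(cls, composition=None, seed: int | None = None, **kwargs):
        """Build from the synthetic generator; returns (model, ground_truth)."""
        from .simulate import default_composition, generate_atlas

        if composition is None:
            composition = default_composition(seed=seed if seed is not None else 1)
        elif seed is not None:
            composition.seed = seed
        counts, truth = generate_atlas(composition)
        return cls(counts, **kwargs), truth

    # -- the fit --------------------------------------------------------------
    def fit(self) -> "AtlasResults":
        cfg = self.config
        raw = self.counts

        qc = qc_mod.compute_cell_qc(
            raw,
            min_umi=cfg.min_umi,
            max_umi=cfg.max_umi,
            min_genes=cfg.min_genes,
            max_mito=cfg.max_mito,
        )
        umi_bound = None
        if cfg.auto_min_umi:
            umi_bound = qc_mod.detect_lower_umi_bound(qc["nUMI"], fallback=cfg.min_umi)
            qc = qc_mod.compute_cell_qc(
                raw,
                min_umi=umi_bound.threshold,
                max_umi=cfg.max_umi,
                min_genes=cfg.min_genes,
                max_mito=cfg.max_mito,
            )
        adata = qc_mod.apply_filters(raw, qc, cfg.min_cells_per_gene)
        cell_qc = qc.loc[adata.obs_names]

        ln = log_normalize(adata)
        genes = list(adata.var_names)
        covariates = pd.DataFrame(
            {
                "replicate": adata.obs.get("replicate", pd.Series("rep", index=adata.obs_names)),
                "nUMI": cell_qc["nUMI"].to_numpy(float),
                "prop_mito": cell_qc["prop_mito"].to_numpy(float),
            },
            index=adata.obs_names,
        )

        sexes = adata.obs["sex"].to_numpy() if "sex" in adata.obs else None
        two_sexes = sexes is not None and len(pd.unique(sexes)) == 2
        var_genes = select_variable_genes(ln, genes, groups=sexes if two_sexes else None)

        # annotation markers are always carried into the scaled layer so the
        # class/FAN/hemilineage rules can read their z-scores
        anno_genes = set()
        for p in self.panels.values():
            anno_genes |= set(p.genes)
        for ms in self.hemilineage_panel["markers"]:
            anno_genes |= set(ms)
        scale_genes = list(dict.fromkeys(list(var_genes) + sorted(anno_genes & set(genes))))
        cols = np.array([genes.index(g) for g in scale_genes])

        if two_sexes:
            sex_values = pd.unique(sexes)
            masks = [sexes == s for s in sex_values]
            blocks = [
                regress_and_scale(ln[m], covariates[m], columns=cols) for m in masks
            ]
            d = min(cfg.dims, min(b.shape[0] for b in blocks) - 1, len(cols) - 1)
            space = cca_reduce(blocks[0], blocks[1], d=d)
            emb = np.empty((adata.n_obs, d))
            emb[np.concatenate([np.flatnonzero(m) for m in masks])] = space.embedding
            scaled = np.empty((adata.n_obs, len(cols)))
            for m, b in zip(masks, blocks):
                scaled[m] = b
        else:
            scaled = regress_and_scale(ln, covariates, columns=cols)
            d = min(cfg.dims, scaled.shape[1] - 1, scaled.shape[0] - 1)
            centred = scaled - scaled.mean(axis=0)
            u, s, _ = np.linalg.svd(centred, full_matrices=False)
            emb = u[:, :d] * s[:d]
            space = None

        clustering = cluster_louvain(
            emb, resolution=cfg.resolution, k_neighbors=cfg.k_neighbors, seed=cfg.seed
        )
        labels = clustering.labels

        mixing = np.nan
        if "replicate" in adata.obs and adata.obs["replicate"].nunique() > 1:
            mixing = batch_mixing_metric(emb, adata.obs["replicate"].to_numpy())

        scaled_prof = cluster_average_expression(scaled, labels, scale_genes, layer="scaled")
        lognorm_prof = cluster_average_expression(ln, labels, genes, layer="lognorm")

        markers_df = None
        if cfg.do_markers:
            if cfg.marker_genes == "all":
                test_genes = None
            elif cfg.marker_genes == "contaminant":
                test_genes = [
                    g
                    for name, p in self.panels.items()
                    for g, r in p.entries.items()
                    if r.startswith("contaminant:")
                ]
            else:
                test_genes = list(cfg.marker_genes)
            markers_df = find_markers_nb(
                adata,
                labels,
                logfc_min=cfg.logfc_min,
                alpha=cfg.alpha,
                genes=test_genes,
            )
        contaminant_flags = (
            ann.flag_contaminant_clusters(markers_df, self.panels) if markers_df is not None else {}
        )

        classes = ann.classify_cluster_class(
            scaled_prof,
            self.panels,
            np_overrides="auto",
            lognorm_profiles=lognorm_prof,
            contaminant_flags=contaminant_flags,
        )
        fan = ann.assign_fan_identity(scaled_prof, ln, genes, labels, classes=classes)
        fan.index = adata.obs_names

        cluster_fan = pd.Series("", index=classes.index, dtype=object)
        for c in classes.index:
            sub = fan.loc[np.asarray(labels) == c, "fan"]
            sub = sub[~sub.isin(["NA"])]
            if len(sub):
                top = sub.value_counts()
                if top.index[0] != "undefined":
                    cluster_fan[c] = top.index[0]

        hemilineages = None
        if cfg.do_hemilineages:
            hemilineages = ann.score_hemilineages(
                scaled_prof, cluster_fan, self.hemilineage_panel
            )

        if all(g in genes for g in ann.HOX_GENES):
            neuromeres = ann.assign_neuromere(ln, genes)
        else:  # no Hox genes in the matrix: neuromere assignment not possible
            neuromeres = pd.Series("", index=range(adata.n_obs), dtype=object, name="neuromere")
        neuromeres.index = adata.obs_names

        # -- neuropeptide census on the cap-free filtered matrix --------------
        census_df = percentile_df = background = None
        if cfg.do_census and "neuropeptide" in self.panels:
            qc_nocap = qc_mod.compute_cell_qc(
                raw,
                min_umi=(umi_bound.threshold if umi_bound else cfg.min_umi),
                max_umi=None,
                min_genes=cfg.min_genes,
                max_mito=cfg.max_mito,
            )
            nocap = qc_mod.apply_filters(raw, qc_nocap, cfg.min_cells_per_gene)
            census_df = census_mod.census_neuropeptides(nocap, self.panels["neuropeptide"])
            percentile_df = census_mod.max_expression_percentile(nocap)
            if cfg.background_gene in adata.var_names:
                background = census_mod.split_background_bonafide(
                    adata, cfg.background_gene, labels
                )

        coexpression = corr_table = None
        if cfg.do_coexpression:
            try:
                rate, pair = coexpr.fan_coexpression_rate(ln, genes)
                coexpression = {"rate": rate, "pairs": pair}
            except ValidationError:
                coexpression = None
            corr_genes = [g for g in ["Antp", "Ubx", "abd-A", "Abd-B", "pros", "Imp", "dati", "mamo"] if g in genes]
            if len(corr_genes) >= 2:
                corr_table = coexpr.pairwise_gene_correlation(ln, corr_genes, all_genes=genes)

        subtypes = {}
        if cfg.do_subtypes:
            subtypes = self._run_subtypes(adata, ln, genes, labels, classes, covariates)

        return AtlasResults(
            model=self,
            adata=adata,
            cell_qc=cell_qc,
            qc_all=qc,
            umi_bound=umi_bound,
            lognorm=ln,
            scaled=scaled,
            scale_genes=scale_genes,
            variable_genes=list(var_genes),
            embedding=emb,
            space=space,
            clustering=clustering,
            labels=labels,
            mixing_score=float(mixing),
            scaled_profiles=scaled_prof,
            lognorm_profiles=lognorm_prof,
            markers=markers_df,
            contaminant_flags=contaminant_flags,
            classes=classes,
            fan=fan,
            cluster_fan=cluster_fan,
            hemilineages=hemilineages,
            neuromeres=neuromeres,
            census=census_df,
            percentiles=percentile_df,
            background_split=background,
            coexpression=coexpression,
            correlations=corr_table,
            subtypes=subtypes,
        )

    def _run_subtypes(self, adata, ln, genes, labels, classes, covariates):
        out = {}
        biomarker_maps = {
            "monoaminergic": {
                "DA": ["DAT"],
                "OA/TA": ["Tdc2", "Tbh"],
                "HA": ["Hdc"],
                "5-HT": ["SerT"],
            },
            "glial": {
                "astrocyte": ["alrm"],
                "surface": ["Indy"],
                "cortex": ["wrapper"],
                "ensheathing": ["Eaat2"],
            },
        }
        for preset_name, preset in PRESETS.items():
            select: dict = {}
            if preset.get("select_genes"):
                select["genes"] = preset["select_genes"]
                if "min_cluster_gene_pct" in preset:
                    select["min_cluster_gene_pct"] = preset["min_cluster_gene_pct"]
            if preset.get("select_classes"):
                select["classes"] = preset["select_classes"]
                select["class_per_cluster"] = classes
            try:
                run = subcluster_cells(
                    adata,
                    labels,
                    select=select,
                    exclude_genes=preset.get("exclude_genes"),
                    dims=preset["dims"],
                    resolution=preset["resolution"],
                    seed=self.config.seed,
                    covariates=covariates,
                )
            except ValidationError:
                continue
            sub_ln = ln[run.cell_index]
            label_by_biomarkers(run, sub_ln, genes, biomarker_maps[preset_name])
            out[preset_name] = run
        return out


@dataclass
class AtlasResults:
    """Fitted atlas: stage tables, derived labels and headline aggregates."""

    model: VNCAtlas
    adata: ad.AnnData
    cell_qc: pd.DataFrame
    qc_all: pd.DataFrame
    umi_bound: object
    lognorm: sp.csr_matrix
    scaled: np.ndarray
    scale_genes: list
    variable_genes: list
    embedding: np.ndarray
    space: object
    clustering: Clustering
    labels: np.ndarray
    mixing_score: float
    scaled_profiles: pd.DataFrame
    lognorm_profiles: pd.DataFrame
    markers: pd.DataFrame | None
    contaminant_flags: dict
    classes: pd.Series
    fan: pd.DataFrame
    cluster_fan: pd.Series
    hemilineages: pd.DataFrame | None
    neuromeres: pd.Series
    census: pd.DataFrame | None
    percentiles: pd.DataFrame | None
    background_split: object
    coexpression: dict | None
    correlations: pd.DataFrame | None
    subtypes: dict = field(default_factory=dict)

    # -- headline aggregates --------------------------------------------------
    @property
    def cell_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cluster": self.labels,
                "class": self.classes.loc[self.labels].to_numpy(),
                "fan": self.fan["fan"].to_numpy(),
                "rule_fired": self.fan["rule_fired"].to_numpy(),
                "neuromere": self.neuromeres.to_numpy(),
            },
            index=self.adata.obs_names,
        )
        if self.hemilineages is not None:
            df["hemilineage"] = (
                self.hemilineages["hemilineage"].reindex(self.labels).fillna("").to_numpy()
            )
        return df

    def fan_percentages(self) -> dict[str, float]:
        """FAN composition of neurons (cells in neuronal + NP clusters), %."""
        tab = self.cell_table
        neurons = tab[tab["class"].isin(["neuronal", "NP"])]
        if neurons.empty:
            return {}
        frac = neurons["fan"].value_counts(normalize=True) * 100.0
        return {k: float(frac.get(k, 0.0)) for k in ("ACh", "GABA", "Glu", "undefined")}

    def glial_cell_percentage(self) -> float:
        tab = self.cell_table
        return float((tab["class"] == "glial").mean() * 100.0)

    def n_neuronal_clusters(self) -> int:
        return int(self.classes.isin(["neuronal", "NP"]).sum())

    def np_census_size(self) -> int:
        return 0 if self.census is None else int(len(self.census))

    def min_np_percentile(self) -> float:
        if self.census is None or self.percentiles is None or self.census.empty:
            return float("nan")
        return float(self.percentiles.loc[self.census["gene"], "percentile"].min())

    def pct_expressing_in_hemilineage(self, hemilineage: str, gene: str) -> float:
        """Percentage of cells in clusters predicted as ``hemilineage``
        detecting ``gene`` (raw count > 0)."""
        if self.hemilineages is None:
            raise ValidationError("hemilineage scoring was not run")
        clusters = self.hemilineages.index[self.hemilineages["hemilineage"] == hemilineage]
        m = np.isin(self.labels, clusters)
        if not m.any():
            return float("nan")
        j = self.adata.var_names.get_loc(gene)
        y = np.asarray(sp.csr_matrix(self.adata.X)[m, j].todense()).ravel()
        return float((y > 0).mean() * 100.0)

    def summary_dict(self) -> dict:
        fan = self.fan_percentages()
        out = {
            "n_cells": int(self.adata.n_obs),
            "n_genes": int(self.adata.n_vars),
            "n_clusters": int(self.clustering.n_clusters),
            "n_neuronal_clusters": self.n_neuronal_clusters(),
            "glial_cell_pct": round(self.glial_cell_percentage(), 3),
            "fan_pct": {k: round(v, 3) for k, v in fan.items()},
            "replicate_mixing": round(self.mixing_score, 4) if np.isfinite(self.mixing_score) else None,
            "np_census_size": self.np_census_size(),
            "min_np_percentile": round(self.min_np_percentile(), 3)
            if np.isfinite(self.min_np_percentile())
            else None,
            "n_marker_rows": None if self.markers is None else int(len(self.markers)),
            "contaminant_clusters": {str(k): v for k, v in self.contaminant_flags.items()},
            "fan_coexpression_rate": None
            if not self.coexpression
            else round(self.coexpression["rate"], 4),
            "config": {k: v for k, v in asdict_safe(self.model.config).items()},
        }
        return out

    def summary(self) -> str:
        s = self.summary_dict()
        fan = s["fan_pct"]
        lines = [
            "VNC atlas fit",
            "=============",
            f"cells retained        {s['n_cells']:>8}",
            f"genes retained        {s['n_genes']:>8}",
            f"clusters              {s['n_clusters']:>8}",
            f"neuronal clusters     {s['n_neuronal_clusters']:>8}",
            f"glial cells (%)       {s['glial_cell_pct']:>8.2f}",
            f"replicate mixing      {s['replicate_mixing'] if s['replicate_mixing'] is not None else 'n/a':>8}",
            "FAN composition of neurons (%):",
        ]
        for k in ("ACh", "GABA", "Glu", "undefined"):
            lines.append(f"  {k:<10} {fan.get(k, float('nan')):>6.2f}")
        lines.append(f"neuropeptide census   {s['np_census_size']:>8}")
        if s["min_np_percentile"] is not None:
            lines.append(f"min NP percentile     {s['min_np_percentile']:>8.2f}")
        if s["fan_coexpression_rate"] is not None:
            lines.append(f"FAN co-expression     {s['fan_coexpression_rate']:>8.3f}")
        return "\n".join(lines)


def asdict_safe(cfg: AtlasConfig) -> dict:
    d = asdict(cfg)
    if isinstance(d.get("marker_genes"), list):
        d["marker_genes"] = list(map(str, d["marker_genes"]))
    return d
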