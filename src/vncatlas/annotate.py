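"""Rule-based annotation: cluster class (neuronal / glial / contaminant /
neuropeptide), fast-acting-neurotransmitter (FAN) identity, hemilineage
prediction, Hox-based neuromere assignment, and contaminant flagging.

The FAN decision procedure is a fixed cascade.  First, cluster-level rules:
cells from clusters with average *scaled* expression above 0.5 for one of an
identity's markers (Gad1/VGAT for GABA, VGlut for glutamate, VAChT/ChAT for
acetylcholine) and below 0 for all markers of the other identities are
assigned wholesale.  Cells from unresolved clusters are assigned one at a
time from their *log-normalised* expression: cholinergic if both VAChT and
ChAT are detected (> 0), or if either exceeds 2; otherwise glutamatergic if
VGlut exceeds 2 and out-competes the other markers; otherwise GABAergic if
Gad1 exceeds 2 and out-competes the others; otherwise undefined.  The
cholinergic branch is deliberately more permissive because VGlut and Gad1
are expressed at much higher absolute levels than the acetylcholine markers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError
from .panels import MarkerPanel, panels_by_name

__all__ = [
    "classify_cluster_class",
    "cluster_fan_rule",
    "assign_fan_identity",
    "score_hemilineages",
    "assign_neuromere",
    "flag_contaminant_clusters",
]

FAN_MARKERS = {"ACh": ["VAChT", "ChAT"], "Glu": ["VGlut"], "GABA": ["Gad1", "VGAT"]}
_ALL_FAN_GENES = ["VAChT", "ChAT", "VGlut", "Gad1", "VGAT"]
HOX_GENES = ["Antp", "Ubx", "abd-A", "Abd-B"]


def _cols(profile: pd.DataFrame, genes: list[str]) -> list[str]:
    return [g for g in genes if g in profile.columns]


def classify_cluster_class(
    scaled_profiles: pd.DataFrame,
    panels: dict[str, MarkerPanel] | list[MarkerPanel] | None = None,
    threshold_neuronal: float = 0.15,
    threshold_glial: float = 0.15,
    np_overrides="auto",
    lognorm_profiles: pd.DataFrame | None = None,
    contaminant_flags: dict | None = None,
) -> pd.Series:
    """Class per cluster: neuronal if any neuronal-panel marker has average
    scaled expression >= threshold; else glial by the same rule with the
    glial panel; contaminant-flagged clusters override; configured (or
    auto-detected) neuropeptide clusters are exempted as class ``NP``;
    everything else is ``other``.

    ``np_overrides="auto"`` marks as NP every otherwise-unclassified cluster
    whose mean log-normalised neuropeptide-panel expression is at least half
    the maximum over clusters (and above 1), mirroring a neurosecretory
    cluster rich in neuropeptides but lacking FAN markers.
    """
    if isinstance(panels, list):
        panels = {p.name: p for p in panels}
    if panels is None:
        panels = panels_by_name()
    neuronal = panels["neuronal"].genes
    glial = panels["glial"].genes
    if not neuronal or not glial:
        raise ValidationError("empty identity panel")

    ncols = _cols(scaled_profiles, neuronal)
    gcols = _cols(scaled_profiles, glial)
    cls = pd.Series("other", index=scaled_profiles.index, dtype=object, name="class")
    if ncols:
        cls[(scaled_profiles[ncols] >= threshold_neuronal).any(axis=1)] = "neuronal"
    if gcols:
        is_glial = (scaled_profiles[gcols] >= threshold_glial).any(axis=1)
        cls[is_glial & (cls == "other")] = "glial"

    if contaminant_flags:
        for c in contaminant_flags:
            if c in cls.index:
                cls[c] = "contaminant"

    if np_overrides == "auto":
        if lognorm_profiles is not None and "neuropeptide" in panels:
            np_cols = _cols(lognorm_profiles, panels["neuropeptide"].genes)
            if np_cols:
                score = lognorm_profiles[np_cols].mean(axis=1)
                cand = (cls == "other") & (score >= 0.5 * score.max()) & (score > 1.0)
                cls[cand] = "NP"
    elif np_overrides:
        for c in np_overrides:
            if c in cls.index:
                cls[c] = "NP"
    return cls


def cluster_fan_rule(scaled_profiles: pd.DataFrame) -> pd.Series:
    """Cluster-level FAN rule: identity marker above 0.5 average scaled
    expression and every other-identity marker below 0.  Returns the FAN
    label per cluster, empty string where unresolved."""
    for g in _ALL_FAN_GENES:
        if g not in scaled_profiles.columns:
            raise ValidationError(f"FAN marker {g!r} missing from profiles")
    out = pd.Series("", index=scaled_profiles.index, dtype=object)
    for fan in ("GABA", "Glu", "ACh"):
        own = FAN_MARKERS[fan]
        others = [g for g in _ALL_FAN_GENES if g not in own]
        hit = (scaled_profiles[own] > 0.5).any(axis=1) & (scaled_profiles[others] < 0).all(axis=1)
        out[hit & (out == "")] = fan
    return out


def assign_fan_identity(
    scaled_profiles: pd.DataFrame,
    lognorm,
    genes,
    labels,
    classes: pd.Series | None = None,
    conjunctive: bool = True,
) -> pd.DataFrame:
    """Per-cell FAN call with the rule that fired.

    ``classes`` restricts assignment to cells of neuronal (and NP) clusters;
    other cells receive fan ``NA``.  ``conjunctive`` selects the reading of
    the cell-level competition clauses ("greater than either A or B"):
    greater than both (default) vs greater than at least one.
    """
    labels = np.asarray(labels)
    genes = list(genes)
    for g in _ALL_FAN_GENES:
        if g not in genes:
            raise ValidationError(f"FAN marker gene {g!r} missing from matrix")
    cluster_fan = cluster_fan_rule(scaled_profiles)

    idx = [genes.index(g) for g in _ALL_FAN_GENES]
    V = lognorm[:, idx]
    if sp.issparse(V):
        V = np.asarray(V.todense())
    vacht, chat, vglut, gad1, _vgat = (V[:, k] for k in range(5))

    fan = np.full(len(labels), "undefined", dtype=object)
    rule = np.full(len(labels), "undefined", dtype=object)

    resolved = pd.Series(cluster_fan.reindex(pd.unique(labels)).fillna(""), dtype=object)
    lab_fan = resolved.loc[labels].to_numpy()
    for f, tag in (("GABA", "cluster_GABA"), ("Glu", "cluster_Glu"), ("ACh", "cluster_ACh")):
        m = lab_fan == f
        fan[m], rule[m] = f, tag

    unresolved = lab_fan == ""
    both = unresolved & (vacht > 0) & (chat > 0)
    fan[both], rule[both] = "ACh", "cell_ACh_both"
    rem = unresolved & ~both
    high = rem & ((vacht > 2) | (chat > 2))
    fan[high], rule[high] = "ACh", "cell_ACh_high"
    rem &= ~high
    if conjunctive:
        glu = rem & (vglut > 2) & (vglut > vacht) & (vglut > gad1)
    else:
        glu = rem & (vglut > 2) & ((vglut > vacht) | (vglut > gad1))
    fan[glu], rule[glu] = "Glu", "cell_Glu"
    rem &= ~glu
    if conjunctive:
        gab = rem & (gad1 > 2) & (gad1 > vacht) & (gad1 > vglut)
    else:
        gab = rem & (gad1 > 2) & ((gad1 > vacht) | (gad1 > vglut))
    fan[gab], rule[gab] = "GABA", "cell_GABA"

    out = pd.DataFrame({"cluster": labels, "fan": fan, "rule_fired": rule})
    if classes is not None:
        neuronal_clusters = set(classes.index[classes.isin(["neuronal", "NP"])])
        non = ~out["cluster"].isin(neuronal_clusters)
        out.loc[non, ["fan", "rule_fired"]] = "NA"
    return out


def score_hemilineages(
    scaled_profiles: pd.DataFrame,
    cluster_fan: pd.Series,
    panel: pd.DataFrame,
    score_min: float = 0.15,
) -> pd.DataFrame:
    """Score each neuronal cluster against the hemilineage marker panel.

    score(h, c) = mean average scaled expression of h's markers minus the
    mean over h's anti-markers (markers of other hemilineages that share at
    least one marker with h).  Candidates are restricted to hemilineages
    whose required FAN matches the cluster's; the argmax is assigned when
    its score reaches ``score_min``, ties or sub-threshold scores are left
    unassigned (runner-up reported).
    """
    if panel.empty:
        raise ValidationError("empty hemilineage panel")
    marker_sets = {h: set(row["markers"]) for h, row in panel.iterrows()}
    anti_sets = {}
    for h, ms in marker_sets.items():
        anti = set()
        for h2, ms2 in marker_sets.items():
            if h2 != h and ms & ms2:
                anti |= ms2 - ms
        anti_sets[h] = anti

    rows = []
    for c in scaled_profiles.index:
        fan = cluster_fan.get(c, "")
        cands = []
        for h, row in panel.iterrows():
            if row["fan"] != fan:
                continue
            pos = _cols(scaled_profiles, sorted(marker_sets[h]))
            if not pos:
                continue
            s = scaled_profiles.loc[c, pos].mean()
            anti = _cols(scaled_profiles, sorted(anti_sets[h]))
            if anti:
                s -= scaled_profiles.loc[c, anti].mean()
            cands.append((float(s), h))
        cands.sort(reverse=True)
        best, runner = (cands[0] if cands else (np.nan, "")), (cands[1] if len(cands) > 1 else (np.nan, ""))
        tie = len(cands) > 1 and abs(best[0] - runner[0]) < 1e-9
        assigned = best[1] if (cands and best[0] >= score_min and not tie) else ""
        rows.append(
            {
                "cluster": c,
                "hemilineage": assigned,
                "score": best[0],
                "best_candidate": best[1],
                "runner_up": runner[1],
                "runner_up_score": runner[0],
                "tie": tie,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def assign_neuromere(
    lognorm,
    genes,
    expr_cut: float = 0.0,
    strict: bool = False,
) -> pd.Series:
    """Per-cell neuromere from differential Hox expression, posterior first:
    abdominal (ANm) if abd-A or Abd-B is detected, else metathoracic if Ubx,
    else mesothoracic if Antp, else prothoracic by exclusion.  ``strict``
    raises the detection cut to 1 and flags cells where both anterior Hox
    genes co-fire as ambiguous."""
    genes = list(genes)
    for g in HOX_GENES:
        if g not in genes:
            raise ValidationError(f"Hox gene {g!r} missing from matrix")
    if strict and expr_cut == 0.0:
        expr_cut = 1.0
    idx = [genes.index(g) for g in HOX_GENES]
    V = lognorm[:, idx]
    if sp.issparse(V):
        V = np.asarray(V.todense())
    antp, ubx, abda, abdb = (V[:, k] for k in range(4))
    out = np.full(V.shape[0], "ProNm", dtype=object)
    out[antp > expr_cut] = "MesoNm"
    out[ubx > expr_cut] = "MetaNm"
    anm = (abda > expr_cut) | (abdb > expr_cut)
    out[anm] = "ANm"
    if strict:
        out[~anm & (antp > expr_cut) & (ubx > expr_cut)] = "ambiguous"
    return pd.Series(out, name="neuromere")


def flag_contaminant_clusters(
    markers: pd.DataFrame,
    panels: dict[str, MarkerPanel] | list[MarkerPanel] | None = None,
    k: int = 5,
) -> dict:
    """Flag clusters where at least ``k`` detected markers belong to one
    contaminant panel.  Returns {cluster: panel_name}."""
    if isinstance(panels, list):
        panels = {p.name: p for p in panels}
    if panels is None:
        panels = panels_by_name()
    contaminant_panels = {
        name: set(p.genes)
        for name, p in panels.items()
        if any(r.startswith("contaminant:") for r in p.entries.values())
    }
    flags: dict = {}
    if markers is None or markers.empty:
        return flags
    for cluster, grp in markers.groupby("cluster"):
        found = set(grp["gene"])
        for name, genes in contaminant_panels.items():
            if len(found & genes) >= k:
                flags[cluster] = name
                break
    return flags
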