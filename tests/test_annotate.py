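"""Class, FAN, hemilineage, neuromere and contaminant rules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from conftest import tiny_composition
from vncatlas.annotate import (
    FAN_MARKERS,
    assign_fan_identity,
    assign_neuromere,
    classify_cluster_class,
    cluster_fan_rule,
    flag_contaminant_clusters,
    score_hemilineages,
)
from vncatlas.errors import ValidationError
from vncatlas.markers import cluster_average_expression
from vncatlas.panels import default_hemilineage_panel, panels_by_name
from vncatlas.preprocess import log_normalize
from vncatlas.simulate import generate_atlas

GENES = ["VAChT", "ChAT", "VGlut", "Gad1", "VGAT", "elav", "repo", "other"]


def _profiles(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


def test_classify_cluster_class_rules():
    prof = _profiles(
        {
            "n": {"elav": 0.3, "repo": -0.1},
            "g": {"elav": -0.5, "repo": 0.4},
            "o": {"elav": -0.2, "repo": -0.2},
        }
    )
    for g in ["nSyb", "para", "VAChT", "ChAT", "Gad1", "VGAT", "VGlut", "noe",
              "alrm", "wrapper", "Indy"]:
        prof[g] = -0.3
    cls = classify_cluster_class(prof, panels_by_name(), np_overrides=None)
    assert cls["n"] == "neuronal"
    assert cls["g"] == "glial"
    assert cls["o"] == "other"


def test_cluster_level_fan_rule():
    cols = ["VAChT", "ChAT", "VGlut", "Gad1", "VGAT"]
    prof = pd.DataFrame(
        [
            [-0.2, -0.1, -0.3, 0.8, 0.6],   # GABA cluster
            [0.9, 0.2, -0.3, -0.2, -0.1],   # ACh cluster (VAChT > 0.5)
            [-0.2, -0.1, 0.3, -0.2, -0.1],  # unresolved (VGlut below 0.5)
            [0.9, -0.1, 0.3, -0.2, -0.1],   # unresolved (VGlut not < 0)
        ],
        columns=cols,
        index=["c0", "c1", "c2", "c3"],
    )
    out = cluster_fan_rule(prof)
    assert list(out) == ["GABA", "ACh", "", ""]


def _cell_case(vacht=0.0, chat=0.0, vglut=0.0, gad1=0.0, vgat=0.0):
    """One cell in an unresolved cluster with the given lognorm values."""
    genes = ["VAChT", "ChAT", "VGlut", "Gad1", "VGAT"]
    ln = np.array([[vacht, chat, vglut, gad1, vgat]])
    prof = pd.DataFrame(np.full((1, 5), -0.1), columns=genes, index=["c"])
    out = assign_fan_identity(prof, ln, genes, np.array(["c"]))
    return out["fan"].iloc[0], out["rule_fired"].iloc[0]


@pytest.mark.parametrize(
    "kwargs,fan,rule",
    [
        (dict(vacht=0.7, chat=0.4), "ACh", "cell_ACh_both"),
        (dict(vacht=2.5), "ACh", "cell_ACh_high"),
        (dict(chat=2.5, gad1=3.0), "ACh", "cell_ACh_high"),
        (dict(vglut=2.5, gad1=2.2), "Glu", "cell_Glu"),
        (dict(gad1=2.5, vglut=1.0), "GABA", "cell_GABA"),
        (dict(), "undefined", "undefined"),
        (dict(vglut=2.5, gad1=3.0), "GABA", "cell_GABA"),  # Gad1 out-competes
    ],
)
def test_cell_level_cascade(kwargs, fan, rule):
    got_fan, got_rule = _cell_case(**kwargs)
    assert (got_fan, got_rule) == (fan, rule)


def test_cascade_is_exhaustive_and_exclusive():
    """Every sign/threshold pattern of the five markers yields exactly one
    call from the closed vocabulary, with a recorded rule."""
    vals = [0.0, 1.0, 2.5]
    genes = ["VAChT", "ChAT", "VGlut", "Gad1", "VGAT"]
    grids = np.array(np.meshgrid(*([vals] * 5))).reshape(5, -1).T
    prof = pd.DataFrame(np.full((1, 5), -0.1), columns=genes, index=["c"])
    out = assign_fan_identity(prof, grids, genes, np.array(["c"] * len(grids)))
    assert set(out["fan"]) <= {"ACh", "Glu", "GABA", "undefined"}
    assert out["fan"].notna().all()
    assert set(out["rule_fired"]) <= {
        "cell_ACh_both", "cell_ACh_high", "cell_Glu", "cell_GABA", "undefined",
    }


def test_conjunctive_vs_disjunctive_reading():
    genes = ["VAChT", "ChAT", "VGlut", "Gad1", "VGAT"]
    prof = pd.DataFrame(np.full((1, 5), -0.1), columns=genes, index=["c"])
    ln = np.array([[0.0, 0.0, 2.5, 3.0, 0.0]])  # VGlut > 2 but Gad1 higher
    conj = assign_fan_identity(prof, ln, genes, np.array(["c"]), conjunctive=True)
    disj = assign_fan_identity(prof, ln, genes, np.array(["c"]), conjunctive=False)
    assert conj["fan"].iloc[0] == "GABA"  # VGlut fails the both-comparison
    assert disj["fan"].iloc[0] == "Glu"  # VGlut > VAChT suffices


def test_missing_marker_gene_named_in_error():
    prof = pd.DataFrame(np.full((1, 5), -0.1), columns=["VAChT", "ChAT", "VGlut", "Gad1", "VGAT"], index=["c"])
    with pytest.raises(ValidationError, match="Gad1"):
        assign_fan_identity(prof, np.zeros((1, 4)), ["VAChT", "ChAT", "VGlut", "VGAT"], np.array(["c"]))


def test_fan_partition_sums_to_one(atlas_fit):
    _, _, res = atlas_fit
    pct = res.fan_percentages()
    assert sum(pct.values()) == pytest.approx(100.0)


def test_fan_recovery_noise_free_and_with_ambient():
    for rate, floor in ((0.0, 1.0), (0.05, 0.95)):
        spec = tiny_composition(n_cells=3000, seed=7, ambient_rate=rate)
        counts, truth = generate_atlas(spec)
        ln = log_normalize(counts)
        genes = list(counts.var_names)
        labels = truth.cells["cluster"].to_numpy()
        fan_genes = [g for g in genes if g in {"VAChT", "ChAT", "VGlut", "Gad1", "VGAT"}]
        cols = np.array([genes.index(g) for g in genes])
        scaled = (lambda M: (M - M.mean(0)) / np.where(M.std(0) > 0, M.std(0), 1))(
            np.asarray(ln.todense())
        )
        prof = cluster_average_expression(scaled, labels, genes, layer="scaled")
        out = assign_fan_identity(prof, ln, genes, labels)
        planted = truth.cells["fan"].to_numpy()
        acc = (out["fan"].to_numpy() == planted).mean()
        assert acc >= floor


def test_hemilineage_worked_example_9b():
    panel = default_hemilineage_panel()
    genes = sorted({g for ms in panel["markers"] for g in ms})
    prof = pd.DataFrame(-0.1, index=["c54"], columns=genes)
    prof.loc["c54", ["Lim3", "tup", "acj6"]] = 1.0
    out = score_hemilineages(prof, pd.Series({"c54": "Glu"}), panel)
    assert out.loc["c54", "hemilineage"] == "9B"


def test_hemilineage_null_profile_unassigned():
    panel = default_hemilineage_panel()
    genes = sorted({g for ms in panel["markers"] for g in ms})
    prof = pd.DataFrame(0.0, index=["c"], columns=genes)
    out = score_hemilineages(prof, pd.Series({"c": "ACh"}), panel)
    assert out.loc["c", "hemilineage"] == ""


def test_hemilineage_recovery_on_fixture(atlas_fit, truth_aligned):
    _, _, res = atlas_fit
    truth_hemi = truth_aligned.groupby(res.labels)["hemilineage"].agg(lambda s: s.mode()[0])
    assignable = truth_hemi[truth_hemi != ""]
    pred = res.hemilineages.loc[assignable.index, "hemilineage"]
    assert (pred == assignable).mean() >= 0.90
    # the 23B clusters carry the planted kn/twz subtype fractions
    kn = res.pct_expressing_in_hemilineage("23B", "kn")
    twz = res.pct_expressing_in_hemilineage("23B", "twz")
    assert kn == pytest.approx(31.0, abs=3.0)
    assert twz == pytest.approx(18.0, abs=3.0)


def test_neuromere_rules_and_monotonicity():
    genes = ["Antp", "Ubx", "abd-A", "Abd-B"]
    ln = np.array(
        [
            [1.0, 0.0, 0.0, 3.0],  # posterior dominance -> ANm
            [0.0, 0.0, 0.0, 0.0],  # exclusion default -> ProNm
            [0.0, 2.0, 0.0, 0.0],  # -> MetaNm
            [2.0, 0.0, 0.0, 0.0],  # -> MesoNm
        ]
    )
    out = assign_neuromere(ln, genes)
    assert list(out) == ["ANm", "ProNm", "MetaNm", "MesoNm"]
    # raising Abd-B never moves a cell out of ANm
    bumped = ln.copy()
    bumped[:, 3] += 2.0
    out2 = assign_neuromere(bumped, genes)
    assert (out2[out == "ANm"] == "ANm").all()
    with pytest.raises(ValidationError, match="Ubx"):
        assign_neuromere(ln[:, [0, 2, 3]], ["Antp", "abd-A", "Abd-B"])


def test_neuromere_strict_mode_flags_coactivation():
    genes = ["Antp", "Ubx", "abd-A", "Abd-B"]
    ln = np.array([[2.0, 2.0, 0.0, 0.0]])
    assert assign_neuromere(ln, genes, strict=True)[0] == "ambiguous"


def test_neuromere_recovery_on_fixture(atlas_fit, truth_aligned):
    _, _, res = atlas_fit
    mask = (truth_aligned["neuromere"] != "").to_numpy()
    agree = (res.neuromeres.to_numpy()[mask] == truth_aligned["neuromere"].to_numpy()[mask]).mean()
    assert agree >= 0.90


def test_contaminant_flagging_thresholds():
    panels = panels_by_name()
    rows = [{"gene": g, "cluster": 99} for g in ["Sgs1", "Sgs3", "Sgs4", "Sgs5", "Sgs7", "Sgs8"]]
    rows += [{"gene": "Sgs1", "cluster": 7}]  # single hit: below k
    flags = flag_contaminant_clusters(pd.DataFrame(rows), panels)
    assert flags == {99: "salivary"}
    assert flag_contaminant_clusters(pd.DataFrame(columns=["gene", "cluster"]), panels) == {}


def test_contaminant_clusters_flagged_on_fixture(atlas_fit, truth_aligned):
    _, _, res = atlas_fit
    assert set(res.contaminant_flags.values()) == {"salivary", "sperm"}
    for cluster in res.contaminant_flags:
        planted = truth_aligned.loc[res.labels == cluster, "class"].mode()[0]
        assert planted == "contaminant"


def test_glial_clusters_recovered_on_fixture(atlas_fit, truth_aligned):
    _, _, res = atlas_fit
    glial_clusters = res.classes.index[res.classes == "glial"]
    for c in glial_clusters:
        assert truth_aligned.loc[res.labels == c, "class"].mode()[0] == "glial"
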