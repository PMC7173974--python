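"""QC gates, debris-trough detection, filter ordering and pseudobulk
concordance."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d

from conftest import tiny_composition
from vncatlas.errors import ValidationError
from vncatlas.qc import (
    apply_filters,
    compute_cell_qc,
    detect_lower_umi_bound,
    pseudobulk_correlate,
)
from vncatlas.simulate import generate_atlas


def _adata(mat, genes=None):
    mat = np.asarray(mat, dtype=np.int64)
    genes = genes or [f"g{j}" for j in range(mat.shape[1])]
    return ad.AnnData(
        X=sp.csr_matrix(mat),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(mat.shape[0])]),
        var=pd.DataFrame(index=genes),
    )


def test_qc_gates_on_hand_built_cells():
    # genes: 2 ordinary + 1 mitochondrial
    genes = ["a", "b", "mt:x"]
    mat = [
        [0, 0, 900],  # all counts mitochondrial -> prop_mito 1.0, fail
        [600, 599, 0],  # nUMI 1199 -> fails the lower bound
        [2500, 2375, 125],  # interior point -> pass
    ]
    qc = compute_cell_qc(_adata(mat, genes), min_genes=1)
    assert qc.loc["c0", "prop_mito"] == 1.0
    assert not qc.loc["c0", "pass"]
    assert qc.loc["c1", "nUMI"] == 1199 and not qc.loc["c1", "pass"]
    assert qc.loc["c2", "pass"]


def test_upper_bound_can_be_disabled():
    mat = [[15000, 0, 0], [2000, 500, 0]]
    capped = compute_cell_qc(_adata(mat), min_genes=1)
    uncapped = compute_cell_qc(_adata(mat), min_genes=1, max_umi=None)
    assert not capped.loc["c0", "pass"]
    assert uncapped.loc["c0", "pass"]
    assert int(uncapped["pass"].sum()) > int(capped["pass"].sum())


def test_empty_matrix_rejected():
    with pytest.raises(ValidationError):
        compute_cell_qc(_adata(np.zeros((0, 3))))


def test_trough_detection_against_brute_force_scan():
    rng = np.random.default_rng(0)
    debris = np.exp(rng.uniform(np.log(300), np.log(1100), size=2000))
    cells = rng.lognormal(np.log(2500), 0.25, size=8000)
    numi = np.concatenate([debris, cells])
    res = detect_lower_umi_bound(numi)
    assert not res.fallback_used
    # independent exhaustive scan of the smoothed histogram between modes
    log = np.log10(numi)
    edges = np.arange(log.min() - 0.15, log.max() + 0.16, 0.01)
    hist, _ = np.histogram(log, bins=edges)
    smooth = gaussian_filter1d(hist.astype(float), sigma=5)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo = np.argmax(smooth[centers < 3.0])  # debris mode
    hi = np.argmax(np.where(centers > 3.1, smooth, -1))  # cell mode
    best = lo + 1 + np.argmin(smooth[lo + 1 : hi])
    assert abs(np.log10(res.threshold) - centers[best]) < 0.06
    assert 800 < res.threshold < 2000


def test_trough_unimodal_falls_back():
    rng = np.random.default_rng(1)
    numi = rng.lognormal(np.log(2500), 0.3, size=5000)
    res = detect_lower_umi_bound(numi)
    assert res.fallback_used
    assert res.threshold == 1200


def test_trough_on_default_fixture_matches_published_interval(atlas_fit):
    _, _, res = atlas_fit
    bound = detect_lower_umi_bound(res.qc_all["nUMI"])
    assert not bound.fallback_used
    assert 1000 <= bound.threshold <= 1200


def test_apply_filters_hand_enumerated():
    # 6 cells x 5 genes; cells c0, c1 fail the nUMI bound; gene g4 is then
    # detected in only 2 surviving cells and is dropped -> 4 x 4
    mat = np.array(
        [
            [100, 0, 0, 0, 50],
            [0, 100, 0, 0, 50],
            [1500, 0, 0, 10, 10],
            [0, 1500, 10, 0, 10],
            [1500, 10, 10, 10, 0],
            [10, 1500, 10, 10, 0],
        ]
    )
    adata = _adata(mat)
    qc = compute_cell_qc(adata, min_umi=1200, max_umi=None, min_genes=1)
    out = apply_filters(adata, qc, min_cells_per_gene=3)
    assert out.shape == (4, 4)
    assert "g4" not in out.var_names


def test_apply_filters_identity_and_idempotence():
    rng = np.random.default_rng(2)
    mat = rng.integers(400, 900, size=(8, 6))
    adata = _adata(mat)
    qc = compute_cell_qc(adata, min_umi=0, max_umi=None, min_genes=1)
    once = apply_filters(adata, qc)
    assert once.shape == adata.shape  # all pass, all genes common
    twice = apply_filters(once, qc.loc[once.obs_names])
    assert twice.shape == once.shape
    assert (sp.csr_matrix(twice.X) != sp.csr_matrix(once.X)).nnz == 0


def test_threshold_monotonicity():
    """Raising any threshold never increases the surviving cell count."""
    counts, _ = generate_atlas(tiny_composition(n_cells=400, seed=9, debris_fraction=0.2))
    survivors = []
    for min_umi in (200, 800, 1200, 2000):
        qc = compute_cell_qc(counts, min_umi=min_umi, min_genes=1)
        survivors.append(int(qc["pass"].sum()))
    assert survivors == sorted(survivors, reverse=True)
    survivors = []
    for max_mito in (0.3, 0.15, 0.05, 0.01):
        qc = compute_cell_qc(counts, max_mito=max_mito, min_genes=1)
        survivors.append(int(qc["pass"].sum()))
    assert survivors == sorted(survivors, reverse=True)


def test_qc_recovers_planted_debris_and_cells(atlas_fit, default_fixture):
    counts, truth = default_fixture
    _, _, res = atlas_fit
    qc = res.qc_all
    debris = truth.cells["is_debris"]
    assert (~qc.loc[debris[debris].index, "pass"]).mean() > 0.95
    assert qc.loc[debris[~debris].index, "pass"].mean() > 0.95


def test_pseudobulk_self_and_replicates():
    counts, _ = generate_atlas(tiny_composition(n_cells=1200, seed=3))
    r, n = pseudobulk_correlate(counts, counts)
    assert r == pytest.approx(1.0)
    assert n == counts.n_vars
    # the two simulated replicates draw cells from the same programs
    r1 = counts[counts.obs["replicate"] == "r1"]
    r2 = counts[counts.obs["replicate"] == "r2"]
    r, _ = pseudobulk_correlate(r1, r2)
    assert r >= 0.9


def test_pseudobulk_disjoint_support_anticorrelated():
    a = pd.Series(np.r_[np.full(100, 50.0), np.zeros(100)], index=[f"g{i}" for i in range(200)])
    b = pd.Series(np.r_[np.zeros(100), np.full(100, 50.0)], index=[f"g{i}" for i in range(200)])
    r, _ = pseudobulk_correlate(a, b)
    assert r <= 0


def test_pseudobulk_requires_shared_genes():
    a = pd.Series(np.ones(50), index=[f"a{i}" for i in range(50)])
    b = pd.Series(np.ones(50), index=[f"b{i}" for i in range(50)])
    with pytest.raises(ValidationError):
        pseudobulk_correlate(a, b)
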