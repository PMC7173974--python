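"""Normalization, scaling, variable genes, CCA, SNN/Louvain and mixing."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from vncatlas.errors import ValidationError
from vncatlas.preprocess import (
    batch_mixing_metric,
    cca_reduce,
    cluster_louvain,
    log_normalize,
    regress_and_scale,
    select_variable_genes,
)


def test_log_normalize_closed_form_and_zeros():
    X = sp.csr_matrix(np.array([[7, 0], [3, 1]], dtype=float))
    ln = log_normalize(X)
    assert ln[0, 0] == pytest.approx(np.log1p(1e4))  # all counts on one gene
    assert ln[0, 1] == 0.0


def test_log_normalize_conserves_scale_per_cell():
    rng = np.random.default_rng(0)
    dense = rng.integers(0, 20, size=(40, 25)).astype(float)
    dense[:, 0] += 1
    X = sp.csr_matrix(dense)
    ln = log_normalize(X)
    sums = np.asarray(sp.csr_matrix(ln).expm1().sum(axis=1)).ravel()
    assert np.allclose(sums, 1e4, rtol=1e-6)


def test_log_normalize_rejects_empty_cell():
    X = sp.csr_matrix(np.array([[0, 0], [1, 2]], dtype=float))
    with pytest.raises(ValidationError):
        log_normalize(X)


def test_log_normalize_duplicate_cell_invariance():
    rng = np.random.default_rng(1)
    row = rng.integers(1, 9, size=(1, 10)).astype(float)
    X = sp.csr_matrix(np.vstack([row, row, rng.integers(1, 9, size=(1, 10))]))
    ln = np.asarray(log_normalize(X).todense())
    assert np.allclose(ln[0], ln[1])


def _cov(n, rng):
    return pd.DataFrame(
        {
            "replicate": np.where(np.arange(n) % 2 == 0, "r1", "r2"),
            "nUMI": rng.normal(2500, 300, n),
            "prop_mito": rng.uniform(0, 0.1, n),
        }
    )


def test_regress_and_scale_contracts():
    rng = np.random.default_rng(2)
    n = 60
    cov = _cov(n, rng)
    X = np.column_stack(
        [
            np.full(n, 3.0),  # constant gene -> all zeros
            0.002 * cov["nUMI"].to_numpy(),  # exactly linear in nUMI -> ~0
            rng.normal(size=n),
        ]
    )
    scaled = regress_and_scale(X, cov)
    assert np.allclose(scaled[:, 0], 0.0)
    assert np.abs(scaled[:, 1]).max() < 1e-8
    assert scaled[:, 2].std() == pytest.approx(1.0, rel=1e-6)


def test_regress_and_scale_clips_outliers():
    rng = np.random.default_rng(3)
    n = 200
    cov = _cov(n, rng)
    x = np.zeros(n)
    x[0] = 100.0  # z-score far beyond the clip bound
    scaled = regress_and_scale(x[:, None], cov, clip=10.0)
    assert scaled.max() == pytest.approx(10.0)


def test_select_variable_genes_contracts():
    rng = np.random.default_rng(4)
    n = 300
    cells_hot = rng.random(n) < 0.3
    cols = {
        "flat": np.full(n, 2.0),  # zero variance -> excluded
        "marker": np.where(cells_hot, 4.0, 0.0) + rng.normal(0, 0.05, n).clip(0),
        "noise": np.abs(rng.normal(1, 0.05, n)),
    }
    for j in range(30):
        cols[f"bg{j}"] = np.abs(rng.normal(1, 0.1, n))
    X = sp.csr_matrix(np.column_stack(list(cols.values())))
    genes = list(cols)
    selected = select_variable_genes(X, genes)
    assert "flat" not in selected
    assert "marker" in selected
    # two identical groups: the intersection equals the per-group set
    groups = np.zeros(n, dtype=int)
    both = select_variable_genes(sp.vstack([X, X]), genes, groups=np.r_[groups, groups + 1])
    assert set(both) == set(select_variable_genes(X, genes))


def test_variable_genes_capture_planted_markers(atlas_fit, default_fixture):
    counts, truth = default_fixture
    _, _, res = atlas_fit
    planted = {"VAChT", "ChAT", "VGlut", "Gad1", "VGAT", "repo", "alrm", "Lk",
               "acj6", "unc-4", "kn", "twz", "Antp", "Ubx", "abd-A", "Abd-B",
               "DAT", "SerT", "Hdc", "Tdc2", "Tbh", "wrapper", "Indy", "Eaat2"}
    got = planted & set(res.variable_genes)
    assert len(got) / len(planted) >= 0.95


def test_cca_self_correlations_are_one():
    rng = np.random.default_rng(5)
    A = rng.normal(size=(80, 40))
    space = cca_reduce(A, A, d=5)
    assert np.allclose(space.canonical_correlations, 1.0, atol=1e-6)


def test_cca_recovers_planted_low_rank_signal():
    rng = np.random.default_rng(6)
    n, g, r = 300, 60, 3
    W = rng.normal(size=(r, g))  # shared gene loadings
    A0 = rng.normal(size=(n, r)) @ W
    B0 = rng.normal(size=(n, r)) @ W
    A = A0 + rng.normal(size=(n, g))
    B = B0 + rng.normal(size=(n, g))
    space = cca_reduce(A, B, d=6)
    s = space.singular_values
    assert s[r - 1] > 2 * s[r]  # spectral gap after the planted rank
    # oracle: the noise-free cross-product is exactly rank 3
    s0 = np.linalg.svd(A0 @ B0.T, compute_uv=False)
    assert s0[r] / s0[0] < 1e-10
    # the leading noisy left subspace aligns with the oracle's
    u0, _, _ = np.linalg.svd(A0 @ B0.T)
    overlap = np.linalg.svd(
        u0[:, :r].T @ np.linalg.svd(A @ B.T)[0][:, :r], compute_uv=False
    )
    assert overlap.min() > 0.8


def test_cca_rejects_degenerate_dimension():
    rng = np.random.default_rng(7)
    A = rng.normal(size=(20, 10))
    with pytest.raises(ValidationError):
        cca_reduce(A, A, d=0)
    with pytest.raises(ValidationError):
        cca_reduce(A, A, d=50)


def _two_blobs(rng, n=100, sep=10.0, d=5):
    a = rng.normal(size=(n, d))
    b = rng.normal(size=(n, d))
    b[:, 0] += sep
    return np.vstack([a, b]), np.r_[np.zeros(n), np.ones(n)]


def test_louvain_two_blobs_exact():
    rng = np.random.default_rng(8)
    emb, truth = _two_blobs(rng)
    clus = cluster_louvain(emb, resolution=1.0, k_neighbors=15, seed=0)
    assert clus.n_clusters == 2
    assert adjusted_rand_score(truth, clus.labels) == 1.0


def test_louvain_single_blob_low_resolution():
    rng = np.random.default_rng(9)
    emb = rng.normal(size=(150, 5))
    clus = cluster_louvain(emb, resolution=0.1, k_neighbors=15, seed=0)
    assert clus.n_clusters == 1


def test_louvain_permutation_invariance():
    rng = np.random.default_rng(10)
    emb, _ = _two_blobs(rng)
    clus = cluster_louvain(emb, resolution=1.0, k_neighbors=30, seed=0)
    perm = rng.permutation(emb.shape[0])
    clus_p = cluster_louvain(emb[perm], resolution=1.0, k_neighbors=30, seed=0)
    assert adjusted_rand_score(clus.labels[perm], clus_p.labels) == 1.0


def test_louvain_resolution_monotonicity():
    rng = np.random.default_rng(11)
    emb = np.vstack([rng.normal(size=(60, 4)) + 6 * k for k in range(4)])
    n_clusters = [
        cluster_louvain(emb, resolution=r, k_neighbors=15, seed=0).n_clusters
        for r in (0.2, 0.5, 1.0, 2.0, 6.0)
    ]
    assert n_clusters == sorted(n_clusters)


def test_louvain_validates_inputs():
    rng = np.random.default_rng(12)
    emb = rng.normal(size=(20, 3))
    with pytest.raises(ValidationError):
        cluster_louvain(emb, resolution=1.0, k_neighbors=25)
    with pytest.raises(ValidationError):
        cluster_louvain(emb, resolution=-1.0, k_neighbors=5)


def test_mixing_metric_random_vs_separated():
    rng = np.random.default_rng(13)
    emb = rng.normal(size=(2000, 5))
    labels = rng.choice(["r1", "r2", "r3"], size=2000)
    assert batch_mixing_metric(emb, labels, k=20) > 0.95
    sep = rng.normal(size=(400, 3))
    sep[:200, 0] += 50
    lab = np.r_[np.full(200, "a"), np.full(200, "b")]
    assert batch_mixing_metric(sep, lab, k=20) <= 0.1
    with pytest.raises(ValidationError):
        batch_mixing_metric(sep, np.full(400, "a"))


def test_default_fixture_is_well_mixed(atlas_fit):
    _, _, res = atlas_fit
    assert res.mixing_score >= 0.85
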