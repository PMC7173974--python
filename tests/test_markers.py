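"""Cluster averages and the negative-binomial marker test, including
agreement with a brute-force maximum-likelihood oracle."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.stats import chi2, nbinom

from vncatlas._nb import nb_lrt
from vncatlas.errors import ValidationError
from vncatlas.markers import cluster_average_expression, find_markers_nb
from vncatlas.preprocess import log_normalize


def test_average_expression_constant_cluster():
    X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]])
    out = cluster_average_expression(X, ["a", "a", "b"], ["g1", "g2"], layer="lognorm")
    assert np.allclose(out.loc["a"], X[0])


def test_average_expression_hand_computed_toy():
    # counts {(2,0),(4,0)} vs {(0,1),(0,3)}: averages taken in expm1 space
    counts = np.array([[2, 0], [4, 0], [0, 1], [0, 3]], dtype=float)
    ln = np.asarray(log_normalize(sp.csr_matrix(counts)).todense())
    out = cluster_average_expression(ln, [0, 0, 1, 1], ["g1", "g2"], layer="lognorm")
    expected_00 = np.log1p(0.5 * (np.expm1(ln[0, 0]) + np.expm1(ln[1, 0])))
    assert out.loc[0, "g1"] == pytest.approx(expected_00)
    assert out.loc[0, "g2"] == 0.0
    assert out.loc[1, "g1"] == 0.0


def test_scaled_layer_average_over_everything_is_zero():
    rng = np.random.default_rng(0)
    Z = rng.normal(size=(50, 4))
    Z -= Z.mean(axis=0)
    out = cluster_average_expression(Z, ["all"] * 50, list("abcd"), layer="scaled")
    assert np.allclose(out.loc["all"], 0.0, atol=1e-12)


def test_average_expression_rejects_empty_cluster():
    with pytest.raises(ValidationError):
        cluster_average_expression(np.ones((2, 2)), [0, 0, 1], ["a", "b"])


# ---- brute-force oracle ----------------------------------------------------


def _oracle_p(y, N, mask):
    """Direct numerical maximisation of the NB likelihood (scipy nbinom),
    independent of the package's Newton/profile path."""

    def nll(params, groups):
        lr = params[:-1]
        a = np.exp(params[-1])
        mu = N * np.exp(lr[groups])
        n = 1.0 / a
        p = n / (n + mu)
        return -nbinom.logpmf(y, n, p).sum()

    g2 = mask.astype(int)
    r0 = np.log(max(y.mean() / N.mean(), 1e-8))
    best_alt = best_null = np.inf
    for a0 in (-2.0, 0.0):
        alt = minimize(nll, [r0, r0, a0], args=(g2,), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
        null = minimize(nll, [r0, a0], args=(np.zeros_like(g2),), method="Nelder-Mead",
                        options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
        best_alt = min(best_alt, alt.fun)
        best_null = min(best_null, null.fun)
    stat = max(2.0 * (best_null - best_alt), 0.0)
    return chi2.sf(stat, df=1)


def test_nb_lrt_matches_brute_force_oracle():
    """On 30 random small cases the profile-likelihood p-value agrees with
    direct numerical likelihood maximisation within 10% relative."""
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(30):
        n = 60
        N = rng.integers(800, 3000, size=n).astype(float)
        mask = np.zeros(n, dtype=bool)
        mask[: rng.integers(10, 30)] = True
        a = rng.uniform(0.1, 0.8)
        fold = rng.uniform(1.0, 4.0)
        r = rng.uniform(1e-3, 5e-3)
        mu = N * r * np.where(mask, fold, 1.0)
        y = rng.poisson(rng.gamma(1.0 / a, a * mu))
        p_pkg, _, _ = nb_lrt(y, N, mask)
        p_oracle = _oracle_p(y, N, mask)
        assert p_pkg == pytest.approx(p_oracle, rel=0.10, abs=1e-12)
        checked += 1
    assert checked == 30


# ---- find_markers_nb -------------------------------------------------------


def _make_dataset(rng, n_in=40, n_out=120, n_genes=30, fold=5.0):
    N = rng.integers(1500, 3000, size=n_in + n_out).astype(float)
    r = rng.uniform(1e-3, 3e-3, size=n_genes)
    mu = N[:, None] * r[None, :]
    mu[:n_in, 0] *= fold  # gene 0 planted in the first cluster
    y = rng.poisson(rng.gamma(1 / 0.35, 0.35 * mu))
    labels = np.r_[np.zeros(n_in, int), np.ones(n_out, int)]
    adata = ad.AnnData(
        X=sp.csr_matrix(y.astype(np.int64)),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(len(N))]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(n_genes)]),
    )
    return adata, labels


def test_planted_marker_detected_null_genes_absent():
    rng = np.random.default_rng(1)
    adata, labels = _make_dataset(rng)
    out = find_markers_nb(adata, labels)
    hit = out[(out["gene"] == "g0") & (out["cluster"] == 0)]
    assert len(hit) == 1
    assert hit["avg_logFC"].iloc[0] > 0.5
    # reported rows all satisfy the printed gates
    assert (out["avg_logFC"] >= 0.5).all()
    assert (out["p_val_adj"] < 0.05).all()
    assert (out["p_val_adj"] >= out["p_val"] - 1e-300).all()
    # a gene with identical rates everywhere is never a marker for cluster 1
    assert out[(out["cluster"] == 1)].empty


def test_pct_fields_hand_computed():
    # in-cluster 3/4 cells express, out-of-cluster 1/8
    y = np.zeros((12, 2))
    y[:3, 0] = 50
    y[4, 0] = 3
    y[:, 1] = 5  # second gene keeps totals positive
    labels = np.r_[np.zeros(4, int), np.ones(8, int)]
    adata = ad.AnnData(
        X=sp.csr_matrix(y.astype(np.int64)),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(12)]),
        var=pd.DataFrame(index=["gA", "gB"]),
    )
    out = find_markers_nb(adata, labels, logfc_min=0.0, alpha=1.0 - 1e-12, min_cells=3)
    row = out[(out["gene"] == "gA") & (out["cluster"] == 0)].iloc[0]
    assert row["pct.1"] == pytest.approx(0.75)
    assert row["pct.2"] == pytest.approx(0.125)


def test_small_cluster_skipped_with_warning():
    rng = np.random.default_rng(2)
    adata, labels = _make_dataset(rng, n_in=2, n_out=40)
    with pytest.warns(UserWarning):
        out = find_markers_nb(adata, labels)
    assert (out["cluster"] != 0).all()
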