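"""Normalization, covariate-regressed scaling, variable-gene selection,
two-group diagonal CCA, SNN/Louvain clustering, and replicate-mixing
diagnostics.

The transformations reproduce a Seurat-2-era workflow: global log
normalization (ln(1 + 1e4 * count / total)), per-gene OLS residuals against
replicate / nUMI / prop_mito followed by z-scoring and clipping, binned
dispersion-z variable genes, diagonal CCA between the two sexes, and
Jaccard-weighted shared-nearest-neighbour Louvain clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, svds
from sklearn.neighbors import NearestNeighbors

from .errors import ValidationError

__all__ = [
    "log_normalize",
    "regress_and_scale",
    "select_variable_genes",
    "ReducedSpace",
    "cca_reduce",
    "Clustering",
    "build_snn_graph",
    "cluster_louvain",
    "batch_mixing_metric",
]


def log_normalize(adata_or_X, scale: float = 1e4) -> sp.csr_matrix:
    """ln(1 + scale * count / cell_total) on the sparse counts.

    Zero counts stay zero; per cell, sum(expm1(lognorm)) == scale.
    """
    X = adata_or_X.X if hasattr(adata_or_X, "X") else adata_or_X
    X = sp.csr_matrix(X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        raise ValidationError("cell with zero total counts (should have been filtered)")
    out = X.copy()
    out.data = np.log1p(scale * out.data / np.repeat(totals, np.diff(out.indptr)))
    return out


def regress_and_scale(
    lognorm,
    covariates: pd.DataFrame,
    clip: float = 10.0,
    columns: np.ndarray | None = None,
) -> np.ndarray:
    """Per gene: OLS residual against the covariates, z-scored, clipped.

    ``covariates`` must contain ``replicate`` (categorical, encoded as
    indicator contrasts), ``nUMI`` and ``prop_mito``.  Constant genes scale
    to all zeros.  ``columns`` restricts the genes (column indices) scaled.
    """
    X = lognorm
    if sp.issparse(X):
        X = np.asarray(X.todense())
    else:
        X = np.asarray(X, dtype=float)
    if columns is not None:
        X = X[:, columns]
    n = X.shape[0]
    if len(covariates) != n:
        raise ValidationError("covariate table does not cover all cells")

    parts = [np.ones((n, 1))]
    if "replicate" in covariates:
        parts.append(pd.get_dummies(covariates["replicate"], drop_first=True).to_numpy(float))
    for col in ("nUMI", "prop_mito"):
        if col in covariates:
            v = covariates[col].to_numpy(float)
            s = v.std()
            parts.append(((v - v.mean()) / (s if s > 0 else 1.0))[:, None])
    D = np.hstack(parts)

    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    resid = X - D @ beta
    sd = resid.std(axis=0)
    # genes fully explained by the covariates (constant genes included) have
    # residual sd at floating-point noise level; they scale to exactly 0
    degenerate = sd <= 1e-10 * np.maximum(X.std(axis=0), 1.0)
    sd[degenerate] = np.inf
    scaled = resid / sd
    np.clip(scaled, -clip, clip, out=scaled)
    return scaled


def _mean_dispersion(lognorm) -> tuple[np.ndarray, np.ndarray]:
    """Mean and dispersion of expm1(lognorm) per gene (expression space)."""
    X = sp.csr_matrix(lognorm)
    E = X.copy()
    E.data = np.expm1(E.data)
    mean = np.asarray(E.mean(axis=0)).ravel()
    sq = E.copy()
    sq.data = sq.data ** 2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean ** 2
    var *= X.shape[0] / max(X.shape[0] - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return mean, disp


def _variable_one_group(lognorm, low_mean, low_disp, n_bins) -> np.ndarray:
    mean, disp = _mean_dispersion(lognorm)
    log_mean = np.log1p(mean)
    log_disp = np.where(disp > 0, np.log(disp), -np.inf)
    finite = np.isfinite(log_disp)
    z = np.full_like(log_disp, -np.inf)
    if finite.sum() >= 2:
        qs = np.quantile(log_mean[finite], np.linspace(0, 1, n_bins + 1))
        qs[-1] += 1e-9
        bins = np.clip(np.searchsorted(qs, log_mean, side="right") - 1, 0, n_bins - 1)
        for b in np.unique(bins[finite]):
            sel = finite & (bins == b)
            mu, sd = log_disp[sel].mean(), log_disp[sel].std()
            z[sel] = (log_disp[sel] - mu) / (sd if sd > 0 else 1.0)
    return (log_mean > low_mean) & (z > low_disp)


def select_variable_genes(
    lognorm,
    genes,
    groups=None,
    low_mean_cut: float = 0.001,
    low_disp_cut: float = 0.001,
    n_bins: int = 20,
) -> list[str]:
    """Genes with binned dispersion z-score above ``low_disp_cut`` and mean
    expression above ``low_mean_cut``.  When two group labels (the sexes)
    are supplied, the per-group selections are intersected."""
    genes = np.asarray(genes)
    X = sp.csr_matrix(lognorm)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 cells")
    if groups is None:
        mask = _variable_one_group(X, low_mean_cut, low_disp_cut, n_bins)
    else:
        groups = np.asarray(groups)
        mask = np.ones(X.shape[1], dtype=bool)
        for g in pd.unique(groups):
            mask &= _variable_one_group(X[groups == g], low_mean_cut, low_disp_cut, n_bins)
    if not mask.any():
        raise ValidationError("no variable genes pass the cutoffs")
    return [g for g, m in zip(genes, mask) if m]


@dataclass
class ReducedSpace:
    embedding: np.ndarray  # cells x d
    d: int
    method: str = "cca"
    canonical_correlations: np.ndarray | None = None
    singular_values: np.ndarray | None = None


def cca_reduce(scaled_a: np.ndarray, scaled_b: np.ndarray, d: int = 45) -> ReducedSpace:
    """Diagonal CCA between two groups sharing the same gene columns.

    The singular decomposition of K = A B^T yields per-cell loadings; the
    two blocks are stacked (A rows first) after rescaling by sqrt(n) so the
    groups live on a common scale.  Canonical correlations are reported as
    the Pearson correlation of the paired gene-space canonical vectors
    A^T u_k and B^T v_k, in decreasing order.
    """
    A = np.asarray(scaled_a, dtype=float)
    B = np.asarray(scaled_b, dtype=float)
    if A.shape[1] != B.shape[1]:
        raise ValidationError("groups must share the same gene columns")
    feasible = min(A.shape[0], B.shape[0], A.shape[1]) - 1
    if d <= 0 or d > feasible:
        raise ValidationError(f"d={d} outside feasible range [1, {feasible}]")

    op = LinearOperator(
        (A.shape[0], B.shape[0]),
        matvec=lambda x: A @ (B.T @ x),
        rmatvec=lambda x: B @ (A.T @ x),
    )
    u, s, vt = svds(op, k=d, v0=np.ones(min(op.shape)))  # fixed start: deterministic
    order = np.argsort(s)[::-1]
    u, v = u[:, order], vt[order].T

    ga, gb = A.T @ u, B.T @ v
    na = np.linalg.norm(ga, axis=0)
    nb = np.linalg.norm(gb, axis=0)
    cancor = np.abs((ga * gb).sum(axis=0)) / np.maximum(na * nb, 1e-300)

    emb = np.vstack([u * np.sqrt(A.shape[0]), v * np.sqrt(B.shape[0])])
    if not np.isfinite(emb).all():
        raise ValidationError("non-finite entries in CCA embedding")
    return ReducedSpace(
        embedding=emb,
        d=d,
        method="cca",
        canonical_correlations=cancor,
        singular_values=s[order],
    )


@dataclass
class Clustering:
    labels: np.ndarray
    resolution: float
    k_neighbors: int
    n_clusters: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_clusters = int(self.labels.max()) + 1 if len(self.labels) else 0


def build_snn_graph(
    embedding: np.ndarray,
    k_neighbors: int = 30,
    prune: float = 1.0 / 15.0,
) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbour graph (self included in the
    neighbour lists, Euclidean metric), pruned below ``prune``."""
    n = embedding.shape[0]
    if k_neighbors >= n:
        raise ValidationError(f"k_neighbors={k_neighbors} >= n cells ({n})")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    rows = np.repeat(np.arange(n), k_neighbors)
    A = sp.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).tocoo()
    jac = shared.data / (2 * k_neighbors - shared.data)
    keep = (jac >= prune) & (shared.row != shared.col)
    return sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))


def cluster_louvain(
    space: ReducedSpace | np.ndarray,
    resolution: float,
    k_neighbors: int = 30,
    seed: int = 42,
    prune: float = 1.0 / 15.0,
) -> Clustering:
    """Louvain modularity optimisation on the SNN graph at the given
    resolution.  Labels are contiguous from 0, ordered by decreasing size.
    Deterministic for a fixed seed."""
    emb = space.embedding if isinstance(space, ReducedSpace) else np.asarray(space)
    if resolution <= 0:
        raise ValidationError("resolution must be positive")
    snn = build_snn_graph(emb, k_neighbors=k_neighbors, prune=prune)
    snn = sp.triu((snn + snn.T) / 2.0, k=1).tocoo()
    g = igraph.Graph(
        n=emb.shape[0],
        edges=list(zip(snn.row.tolist(), snn.col.tolist())),
        edge_attrs={"weight": snn.data.tolist()},
    )
    import random as _random

    igraph.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    # relabel by decreasing cluster size, first-seen order breaking ties
    sizes = pd.Series(labels).value_counts(sort=True)
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[v] for v in labels])
    return Clustering(labels=labels, resolution=resolution, k_neighbors=k_neighbors)


def batch_mixing_metric(
    space: ReducedSpace | np.ndarray,
    replicate_labels,
    k: int = 30,
) -> float:
    """Replicate-mixing score in [0, 1]: the mean over cells of the fraction
    of k nearest neighbours from *other* replicates, normalised by its
    expectation under perfect mixing.  1 = perfectly mixed."""
    emb = space.embedding if isinstance(space, ReducedSpace) else np.asarray(space)
    labels = np.asarray(replicate_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 replicates")
    n = emb.shape[0]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    idx = idx[:, 1:]  # drop self
    other = (labels[idx] != labels[:, None]).mean(axis=1)
    frac = pd.Series(counts / n, index=uniq)
    expected = 1.0 - frac.loc[labels].to_numpy()
    score = float(np.mean(other / expected))
    return min(score, 1.0)
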