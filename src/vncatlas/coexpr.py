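"""Pairwise gene-correlation tables (cell- and cluster-level) and the
fast-acting-neurotransmitter marker co-expression rate."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import t as t_dist

from .errors import ValidationError

__all__ = ["pairwise_gene_correlation", "fan_coexpression_rate"]

_FAN_TRIO = ["VAChT", "VGlut", "Gad1"]


def pairwise_gene_correlation(
    values,
    genes,
    all_genes=None,
    level: str = "cell",
) -> pd.DataFrame:
    """Long-format symmetric Pearson correlation table for a gene subset.

    ``values`` is a cells x genes (level="cell") or clusters x genes
    (level="cluster") expression matrix with column names ``all_genes``
    (defaults to ``genes``).  Constant genes yield records flagged
    ``undefined=True`` with r = NaN rather than being dropped.  Bonferroni-
    adjusted two-sided p-values (t approximation) are reported, not gating.
    """
    genes = list(genes)
    cols = list(all_genes) if all_genes is not None else genes
    V = values
    if sp.issparse(V):
        V = np.asarray(V.todense())
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 observations")
    missing = [g for g in genes if g not in cols]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    idx = [cols.index(g) for g in genes]
    M = V[:, idx]
    sd = M.std(axis=0)
    Z = (M - M.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    C = Z.T @ Z / n

    n_pairs = len(genes) * (len(genes) - 1) // 2
    rows = []
    for a in range(len(genes)):
        for b in range(a, len(genes)):
            und = sd[a] == 0 or sd[b] == 0
            r = np.nan if und else float(np.clip(C[a, b], -1.0, 1.0))
            if und or abs(r) >= 1.0:
                p = np.nan if und else 0.0
            else:
                tt = r * np.sqrt((n - 2) / (1 - r**2))
                p = 2 * t_dist.sf(abs(tt), n - 2)
            rows.append(
                {
                    "gene_a": genes[a],
                    "gene_b": genes[b],
                    "level": level,
                    "r": r,
                    "n": n,
                    "p": p,
                    "p_adj": min(p * max(n_pairs, 1), 1.0) if np.isfinite(p) else np.nan,
                    "undefined": und,
                }
            )
    return pd.DataFrame(rows)


def fan_coexpression_rate(
    lognorm,
    genes,
    markers: list[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of cells detecting (> 0) at least two of the three FAN
    markers, plus the pairwise co-detection matrix (fraction of cells
    detecting both genes of each pair)."""
    markers = markers or _FAN_TRIO
    genes = list(genes)
    for g in markers:
        if g not in genes:
            raise ValidationError(f"FAN marker {g!r} missing from matrix")
    V = lognorm
    if sp.issparse(V):
        V = np.asarray(V.todense())
    D = V[:, [genes.index(g) for g in markers]] > 0
    rate = float((D.sum(axis=1) >= 2).mean())
    pair = pd.DataFrame(
        (D.astype(float).T @ D.astype(float)) / D.shape[0],
        index=markers,
        columns=markers,
    )
    return rate, pair
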