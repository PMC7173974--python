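import warnings

import numpy as np
import pandas as pd
import pytest

from vncatlas.model import VNCAtlas
from vncatlas.simulate import (
    ClusterSpec,
    CompositionSpec,
    MarkerSpec,
    ReplicateSpec,
    default_composition,
    generate_atlas,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_fixture():
    """The packaged desk-scale atlas (seed 42): counts + planted truth."""
    spec = default_composition(seed=42)
    counts, truth = generate_atlas(spec)
    return counts, truth


@pytest.fixture(scope="session")
def atlas_fit(default_fixture):
    """Full pipeline fit of the default fixture, shared across tests."""
    counts, truth = default_fixture
    res = VNCAtlas(counts).fit()
    return counts, truth, res


@pytest.fixture(scope="session")
def truth_aligned(atlas_fit):
    """Ground-truth rows for the QC-surviving cells, in matrix order."""
    _, truth, res = atlas_fit
    return truth.cells.loc[res.adata.obs_names]


def tiny_composition(
    n_cells=2000,
    n_genes=300,
    seed=0,
    ambient_rate=0.0,
    debris_fraction=0.0,
    dispersion=0.35,
    fan_fracs=(0.4, 0.35, 0.25),
):
    """A 3-cluster (ACh / GABA / Glu) composition for cheap unit tests."""
    fan_markers = {
        "ACh": [MarkerSpec("VAChT", 8.0), MarkerSpec("ChAT", 6.0)],
        "GABA": [MarkerSpec("Gad1", 25.0), MarkerSpec("VGAT", 12.0)],
        "Glu": [MarkerSpec("VGlut", 25.0)],
    }
    structural = [MarkerSpec("elav", 8.0), MarkerSpec("nSyb", 8.0), MarkerSpec("noe", 6.0)]
    clusters = [
        ClusterSpec(
            label=f"c_{fan}",
            fraction=f,
            class_="neuronal",
            fan=fan,
            markers=structural + fan_markers[fan],
            dispersion=dispersion,
        )
        for fan, f in zip(("ACh", "GABA", "Glu"), fan_fracs)
    ]
    reps = [ReplicateSpec("r1", "F", 0.5), ReplicateSpec("r2", "M", 0.5)]
    return CompositionSpec(
        clusters=clusters,
        n_genes=n_genes,
        replicates=reps,
        n_cells=n_cells,
        ambient_rate=ambient_rate,
        debris_fraction=debris_fraction,
        seed=seed,
    )


def random_counts_adata(rng, n_cells=50, n_genes=30, density=0.3, max_count=20):
    """Small random integer count matrix as AnnData."""
    import anndata as ad
    import scipy.sparse as sp

    X = rng.integers(1, max_count, size=(n_cells, n_genes))
    X = X * (rng.random((n_cells, n_genes)) < density)
    X[:, 0] += 1  # keep every cell non-empty
    return ad.AnnData(
        X=sp.csr_matrix(X.astype(np.int64)),
        obs=pd.DataFrame(index=[f"BC{i:04d}" for i in range(n_cells)]),
        var=pd.DataFrame(index=[f"G{j:03d}" for j in range(n_genes)]),
    )
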