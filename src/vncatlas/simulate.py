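"""Synthetic VNC atlas generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: ~120 transcriptionally distinct clusters drawn from a negative
binomial noise model (per-cell library size log-normal, per-cluster
dispersion), planted marker genes, mitochondrial fractions, a neuropeptide
cluster with extreme per-gene expression, monoaminergic and glial
sub-structure, low-UMI debris barcodes, a mild per-replicate batch effect,
and ambient-RNA contamination.

Noise model, per cell i in cluster c:

    library_i   ~ LogNormal(log(median * cluster_factor), sigma)
    mito_i      ~ Beta(a, b)                      (expected mito fraction)
    intensity   = base_program_c * jitter_c [* subtype jitter] + markers
    mean_ig     = (1 - mito_i) * library_i * intensity_g / sum(intensity)
    count_ig    ~ NB(mean_ig, dispersion_c)       (Gamma-Poisson mixture)

then ambient contamination adds, for each cell, Poisson(rate * nUMI_i)
counts multinomially distributed over the ambient profile.  The ambient
profile is the library-weighted average transcriptome with the neuropeptide
cluster up-weighted, modelling preferential rupture of fragile
high-output neurosecretory cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .errors import ValidationError
from .panels import default_panels

__all__ = [
    "MarkerSpec",
    "SubtypeSpec",
    "ClusterSpec",
    "ReplicateSpec",
    "CompositionSpec",
    "GroundTruth",
    "generate_atlas",
    "spike_ambient",
    "default_composition",
]


@dataclass
class MarkerSpec:
    """A planted marker: expected UMI count per expressing cell at the
    reference library size, and the fraction of cluster cells expressing it.
    ``n_cells_exact`` plants the marker in exactly that many cells."""

    gene: str
    mean_count: float
    fraction: float = 1.0
    n_cells_exact: int | None = None

    def validate(self) -> None:
        if not self.gene:
            raise ValidationError("marker with empty gene symbol")
        if self.mean_count < 0:
            raise ValidationError(f"{self.gene}: negative mean_count")
        if not (0.0 < self.fraction <= 1.0):
            raise ValidationError(f"{self.gene}: expressing fraction must be in (0, 1]")


@dataclass
class SubtypeSpec:
    label: str
    fraction: float
    markers: list[MarkerSpec] = field(default_factory=list)
    jitter: float = 0.3


@dataclass
class ClusterSpec:
    label: str
    fraction: float
    class_: str = "neuronal"  # neuronal | glial | contaminant | NP | other
    fan: str = "none"  # ACh | Glu | GABA | none
    hemilineage: str | None = None
    neuromere: str | None = None
    subtype: str | None = None
    markers: list[MarkerSpec] = field(default_factory=list)
    subtypes: list[SubtypeSpec] = field(default_factory=list)
    dispersion: float = 0.35
    libsize_factor: float = 1.0
    program_jitter: float = 0.5

    def validate(self) -> None:
        if self.fraction <= 0:
            raise ValidationError(f"cluster {self.label}: non-positive fraction")
        if self.dispersion < 0:
            raise ValidationError(f"cluster {self.label}: negative dispersion")
        if self.class_ not in {"neuronal", "glial", "contaminant", "NP", "other"}:
            raise ValidationError(f"cluster {self.label}: unknown class {self.class_}")
        if self.fan not in {"ACh", "Glu", "GABA", "none"}:
            raise ValidationError(f"cluster {self.label}: unknown fan {self.fan}")
        for m in self.markers:
            m.validate()
        if self.subtypes:
            tot = sum(s.fraction for s in self.subtypes)
            if abs(tot - 1.0) > 1e-9:
                raise ValidationError(
                    f"cluster {self.label}: subtype fractions sum to {tot}, not 1"
                )
            for s in self.subtypes:
                for m in s.markers:
                    m.validate()


@dataclass
class ReplicateSpec:
    label: str
    sex: str  # "F" | "M"
    fraction: float


@dataclass
class CompositionSpec:
    """Full generator configuration; the packaged default mirrors the
    composition of the published atlas (see :func:`default_composition`)."""

    clusters: list[ClusterSpec]
    n_genes: int
    replicates: list[ReplicateSpec]
    n_cells: int = 12000
    mito_gene_count: int = 10
    ambient_rate: float = 0.02
    ambient_np_weight: float = 0.15
    debris_fraction: float = 0.10
    median_libsize: float = 2500.0
    libsize_sigma: float = 0.30
    mito_beta: tuple[float, float] = (2.5, 47.5)
    batch_sigma: float = 0.05
    base_exponent: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if not self.clusters:
            raise ValidationError("composition has no clusters")
        tot = sum(c.fraction for c in self.clusters)
        if abs(tot - 1.0) > 1e-9:
            raise ValidationError(f"cluster fractions sum to {tot}, not 1 +- 1e-9")
        if not (0.0 <= self.ambient_rate < 1.0):
            raise ValidationError("ambient_rate must be in [0, 1)")
        if not (0.0 <= self.debris_fraction < 1.0):
            raise ValidationError("debris_fraction must be in [0, 1)")
        if self.n_cells <= 0 or self.n_genes <= 0 or self.mito_gene_count < 0:
            raise ValidationError("all counts must be positive")
        rtot = sum(r.fraction for r in self.replicates)
        if abs(rtot - 1.0) > 1e-9:
            raise ValidationError("replicate fractions must sum to 1")
        for c in self.clusters:
            c.validate()
        named = self.named_genes()
        if self.n_genes < len(named) + self.mito_gene_count + 10:
            raise ValidationError(
                f"n_genes={self.n_genes} too small for {len(named)} planted genes "
                f"+ {self.mito_gene_count} mitochondrial genes"
            )

    def named_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.clusters:
            for m in c.markers:
                seen.setdefault(m.gene)
            for s in c.subtypes:
                for m in s.markers:
                    seen.setdefault(m.gene)
        for g in ("roX1", "roX2"):
            seen.setdefault(g)
        return list(seen)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CompositionSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["clusters"] = [
            ClusterSpec(
                **{
                    **c,
                    "markers": [MarkerSpec(**m) for m in c.get("markers", [])],
                    "subtypes": [
                        SubtypeSpec(
                            **{
                                **s,
                                "markers": [MarkerSpec(**m) for m in s.get("markers", [])],
                            }
                        )
                        for c_s in [c.get("subtypes", [])]
                        for s in c_s
                    ],
                }
            )
            for c in payload["clusters"]
        ]
        payload["replicates"] = [ReplicateSpec(**r) for r in payload["replicates"]]
        if "mito_beta" in payload:
            payload["mito_beta"] = tuple(payload["mito_beta"])
        return cls(**payload)


@dataclass
class GroundTruth:
    """Planted labels: one row per simulated barcode, plus a per-gene table."""

    cells: pd.DataFrame
    genes: pd.DataFrame
    ambient_profile: np.ndarray
    composition: CompositionSpec


def base_program(n_filler: int, exponent: float = 0.6) -> np.ndarray:
    """The shared rank/abundance profile of the background transcriptome:
    a power law with a long exponentially decaying low-expression tail over
    the last quarter of genes (real transcriptomes are dominated by weakly
    detected genes, which anchors the dispersion binning and gives the
    few-cells gene filter something to act on)."""
    ranks = np.arange(1, n_filler + 1, dtype=float)
    base = (ranks + 10.0) ** (-exponent)
    tail_start = int(0.75 * n_filler)
    span = max(n_filler - tail_start, 1)
    decay = np.ones(n_filler)
    decay[tail_start:] = np.exp(-6.0 * (ranks[tail_start:] - tail_start) / span)
    base *= decay
    return base / base.sum()


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean `mean` and variance mean + a*mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def _ambient_draw(
    rng: np.random.Generator, n_per_cell: np.ndarray, profile: np.ndarray, n_genes: int
) -> sp.csr_matrix:
    """Sample per-cell multinomial ambient counts as one pooled categorical
    draw, then scatter back to (cell, gene) pairs."""
    total = int(n_per_cell.sum())
    if total == 0:
        return sp.csr_matrix((len(n_per_cell), n_genes), dtype=np.int64)
    gene_idx = rng.choice(n_genes, size=total, p=profile)
    cell_idx = np.repeat(np.arange(len(n_per_cell)), n_per_cell)
    data = np.ones(total, dtype=np.int64)
    return sp.csr_matrix(
        (data, (cell_idx, gene_idx)), shape=(len(n_per_cell), n_genes)
    )


def spike_ambient(
    adata: ad.AnnData,
    ambient_profile: np.ndarray | pd.Series,
    rate: float,
    seed: int,
) -> ad.AnnData:
    """Add ambient-RNA contamination: for each cell, Poisson(rate x nUMI)
    extra counts distributed multinomially over ``ambient_profile``.

    Returns a new AnnData; the input is left untouched.
    """
    if rate < 0 or rate >= 1:
        raise ValidationError(f"ambient rate must be in [0, 1), got {rate}")
    profile = np.asarray(
        ambient_profile.values if isinstance(ambient_profile, pd.Series) else ambient_profile,
        dtype=float,
    )
    if profile.shape[0] != adata.n_vars:
        raise ValidationError("ambient profile length does not match gene count")
    if (profile < 0).any():
        raise ValidationError("ambient profile has a negative entry")
    s = profile.sum()
    if not np.isclose(s, 1.0, atol=1e-6):
        raise ValidationError("ambient profile must sum to 1")
    profile = profile / s
    out = adata.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    numi = np.asarray(out.X.sum(axis=1)).ravel()
    n_add = rng.poisson(rate * numi)
    added = _ambient_draw(rng, n_add, profile, out.n_vars)
    out.X = (sp.csr_matrix(out.X) + added).astype(np.int64)
    return out


def generate_atlas(spec: CompositionSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate a count matrix plus ground truth from a composition.

    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # ----- gene universe -----------------------------------------------------
    named = spec.named_genes()
    mito_genes = [f"mt:gene{i + 1}" for i in range(spec.mito_gene_count)]
    n_filler = spec.n_genes - len(named) - len(mito_genes)
    filler = [f"CG{50000 + i}" for i in range(n_filler)]
    genes = named + filler + mito_genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    filler_ix = np.array([gene_idx[g] for g in filler])
    mito_ix = np.array([gene_idx[g] for g in mito_genes], dtype=int)

    base = base_program(n_filler, spec.base_exponent)
    mito_profile = 1.0 / (np.arange(spec.mito_gene_count) + 1.0)
    mito_profile /= mito_profile.sum()

    # ----- cells per cluster, replicates -------------------------------------
    fracs = np.array([c.fraction for c in spec.clusters])
    sizes = rng.multinomial(spec.n_cells, fracs / fracs.sum())
    rep_fracs = np.array([r.fraction for r in spec.replicates])
    batch = rng.lognormal(0.0, spec.batch_sigma, size=(len(spec.replicates), G))
    male_reps = np.array([r.sex == "M" for r in spec.replicates])
    rox_ix = np.array([gene_idx["roX1"], gene_idx["roX2"]])

    ref = spec.median_libsize
    blocks: list[np.ndarray] = []
    truth_rows: list[pd.DataFrame] = []

    for c, nc in zip(spec.clusters, sizes):
        if nc == 0:
            continue
        jitter = rng.lognormal(0.0, c.program_jitter, size=n_filler)
        u0 = np.zeros(G)
        u0[filler_ix] = base * jitter

        U = np.tile(u0, (nc, 1))

        # subtype blocks: contiguous slices with their own jitter + markers
        subtype_label = np.full(nc, c.subtype if c.subtype else "", dtype=object)
        if c.subtypes:
            bounds = np.round(np.cumsum([0.0] + [s.fraction for s in c.subtypes]) * nc).astype(int)
            bounds[-1] = nc
            for s, lo, hi in zip(c.subtypes, bounds[:-1], bounds[1:]):
                sj = rng.lognormal(0.0, s.jitter, size=n_filler)
                U[lo:hi][:, filler_ix] *= sj
                subtype_label[lo:hi] = s.label
                for m in s.markers:
                    _plant(rng, U[lo:hi], gene_idx[m.gene], m, ref)

        for m in c.markers:
            _plant(rng, U, gene_idx[m.gene], m, ref)

        rep = rng.choice(len(spec.replicates), size=nc, p=rep_fracs)
        U *= batch[rep]
        male = male_reps[rep]
        U[np.ix_(male, rox_ix)] += 5.0 / ref

        lib = rng.lognormal(np.log(ref * c.libsize_factor), spec.libsize_sigma, size=nc)
        mito_f = rng.beta(*spec.mito_beta, size=nc)
        row_sum = U.sum(axis=1, keepdims=True)
        mean = U / row_sum * ((1.0 - mito_f) * lib)[:, None]
        mean[:, mito_ix] = np.outer(mito_f * lib, mito_profile)

        counts = _nb_sample(rng, mean, c.dispersion)
        blocks.append(counts)
        truth_rows.append(
            pd.DataFrame(
                {
                    "cluster": c.label,
                    "class": c.class_,
                    "fan": c.fan,
                    "hemilineage": c.hemilineage or "",
                    "neuromere": c.neuromere or "",
                    "subtype": subtype_label,
                    "replicate": [spec.replicates[r].label for r in rep],
                    "sex": [spec.replicates[r].sex for r in rep],
                    "is_debris": False,
                }
            )
        )

    counts = np.vstack(blocks)
    truth = pd.concat(truth_rows, ignore_index=True)

    # ----- ambient profile: rupture-weighted average transcriptome -----------
    col_tot = counts.sum(axis=0).astype(float)
    global_profile = col_tot / col_tot.sum()
    np_mask = (truth["class"] == "NP").to_numpy()
    if np_mask.any() and spec.ambient_np_weight > 0:
        np_tot = counts[np_mask].sum(axis=0).astype(float)
        np_profile = np_tot / np_tot.sum()
        ambient = (1.0 - spec.ambient_np_weight) * global_profile
        ambient += spec.ambient_np_weight * np_profile
    else:
        ambient = global_profile.copy()
    ambient /= ambient.sum()

    if spec.ambient_rate > 0:
        numi = counts.sum(axis=1)
        n_add = rng.poisson(spec.ambient_rate * numi)
        counts = counts + np.asarray(
            _ambient_draw(rng, n_add, ambient, G).todense()
        )

    # ----- debris barcodes: ambient-only draws at low nUMI -------------------
    n_debris = int(round(spec.debris_fraction * spec.n_cells))
    if n_debris:
        debris_numi = np.exp(
            rng.uniform(np.log(300.0), np.log(1000.0), size=n_debris)
        ).astype(int)
        debris = np.asarray(_ambient_draw(rng, debris_numi, ambient, G).todense())
        counts = np.vstack([counts, debris])
        rep = rng.choice(len(spec.replicates), size=n_debris, p=rep_fracs)
        truth = pd.concat(
            [
                truth,
                pd.DataFrame(
                    {
                        "cluster": "",
                        "class": "debris",
                        "fan": "none",
                        "hemilineage": "",
                        "neuromere": "",
                        "subtype": "",
                        "replicate": [spec.replicates[r].label for r in rep],
                        "sex": [spec.replicates[r].sex for r in rep],
                        "is_debris": True,
                    }
                ),
            ],
            ignore_index=True,
        )

    # ----- shuffle barcodes so cluster structure is not positional -----------
    order = rng.permutation(len(truth))
    counts = counts[order]
    truth = truth.iloc[order].reset_index(drop=True)
    barcodes = [f"BC{i:06d}" for i in range(len(truth))]
    truth.index = pd.Index(barcodes, name="barcode")

    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=truth[["replicate", "sex"]].copy(),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )

    role_map: dict[str, str] = {}
    for p in default_panels():
        for g, r in p.entries.items():
            role_map.setdefault(g, r)
    gene_table = pd.DataFrame(
        {
            "role": [role_map.get(g, "") for g in genes],
            "is_mito": [g.startswith("mt:") for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return adata, GroundTruth(truth, gene_table, ambient, spec)


def _plant(
    rng: np.random.Generator,
    U: np.ndarray,
    col: int,
    m: MarkerSpec,
    ref_lib: float,
) -> None:
    """Add a marker's intensity to the expressing subset of rows of U.

    Fractional markers are planted in an exact-count subset (hypergeometric
    planting) so the realised expressing fraction equals the specification."""
    n = U.shape[0]
    if m.n_cells_exact is not None:
        k = min(m.n_cells_exact, n)
        rows = rng.choice(n, size=k, replace=False)
    elif m.fraction >= 1.0:
        rows = slice(None)
    else:
        k = int(round(m.fraction * n))
        rows = rng.choice(n, size=k, replace=False)
    U[rows, col] += m.mean_count / ref_lib


# ---------------------------------------------------------------------------
# Packaged default composition
# ---------------------------------------------------------------------------

# fraction of NEURONS per FAN, mirroring the printed 40/38/18/4 split
_FAN_PLAN = [("ACh", 44, 0.40), ("GABA", 42, 0.38), ("Glu", 20, 0.18)]
_NEUROMERE_CYCLE = (
    ["ProNm"] * 8 + ["MesoNm"] * 5 + ["MetaNm"] * 4 + ["ANm"] * 3
)

_FAN_MARKERS = {
    "ACh": [MarkerSpec("VAChT", 8.0), MarkerSpec("ChAT", 6.0)],
    "GABA": [MarkerSpec("Gad1", 25.0), MarkerSpec("VGAT", 12.0)],
    "Glu": [MarkerSpec("VGlut", 25.0)],
}
_STRUCTURAL = [
    MarkerSpec("elav", 8.0),
    MarkerSpec("nSyb", 8.0),
    MarkerSpec("noe", 6.0),
    MarkerSpec("para", 4.0),
]
# FAN-undefined neuronal clusters carry no transporter markers, so their
# neuronal identity must be legible from the pan-neuronal genes alone; they
# are planted clearly above the atlas-wide average, as in deeply neuronal
# monoaminergic/interneuron types
_STRUCTURAL_STRONG = [
    MarkerSpec("elav", 14.0),
    MarkerSpec("nSyb", 14.0),
    MarkerSpec("noe", 10.0),
    MarkerSpec("para", 7.0),
]
_HOX = {
    "ProNm": [],
    "MesoNm": [MarkerSpec("Antp", 6.0, 0.95)],
    "MetaNm": [MarkerSpec("Ubx", 6.0, 0.95)],
    "ANm": [
        MarkerSpec("abd-A", 5.0, 0.90),
        MarkerSpec("Abd-B", 5.0, 0.90),
        MarkerSpec("Ubx", 2.0, 0.40),
    ],
}
# hemilineage -> (fan, marker genes); mirrors the packaged hemilineage panel
_HEMI_SCHEDULE = {
    "ACh": [("23B", ["acj6", "unc-4"])] * 4
    + [("8B", ["acj6", "Lim3"])] * 3
    + [("7B", ["unc-4", "TfAP-2"])] * 3
    + [("12A", ["unc-4", "vvl"])] * 3
    + [("11A", ["ey", "sens"])] * 3
    + [("17A", ["D", "unc-4"])] * 3,
    "GABA": [("0A", ["Dbx", "hth"])] * 4
    + [("19A", ["Dbx", "dac"])] * 4
    + [("13A", ["vg", "dac"])] * 4
    + [("6B", ["en", "sens"])] * 4,
    "Glu": [("9B", ["acj6", "Lim3", "tup"])] * 3
    + [("8A", ["ems", "ey"])] * 3
    + [("24B", ["ems", "toy"])] * 3
    + [("15B", ["eve", "grn"])] * 2,
}

_NP_GENES = [
    "Lk", "sNPF", "spab", "MIP", "CCHa1", "CCHa2", "Ilp7", "Proc", "AstA",
    "AstC", "Gpa2", "Gpb5", "Dh31", "Dh44", "Tk", "NPF", "Ms", "Dsk", "Burs",
    "Pburs", "CCAP", "Crz", "FMRFa", "Hug", "Nplp1", "SIFa", "Capa",
    "Orcokinin",
]

_SALIVARY = ["Sgs1", "Sgs3", "Sgs4", "Sgs5", "Sgs7", "Sgs8", "Eig71Ee", "ng1"]
_SPERM = ["dj", "Mst35Ba", "Mst35Bb", "Mst57Da", "Mst84Da", "Mst84Db", "Mst98Ca", "ocn"]


def _weights(n: int, lo: float = 0.7, span: float = 0.6) -> np.ndarray:
    """Deterministic mildly varying cluster-size weights (golden-ratio strides)."""
    phi = 0.6180339887498949
    return lo + span * np.modf(np.arange(1, n + 1) * phi)[0]


def default_composition(
    n_cells: int = 12000,
    n_genes: int = 1500,
    seed: int = 1,
    ambient_rate: float = 0.02,
    debris_fraction: float = 0.10,
    full_scale: bool = False,
) -> CompositionSpec:
    """The packaged default fixture: 120 clusters (110 neuronal incl. one
    neuropeptide and one monoaminergic cluster, 5 glial, 2 contaminant,
    3 unannotated), FAN composition 40/38/18/4, glia 3.6% of cells.

    ``full_scale=True`` emits the published atlas size (26,768 cells);
    the default is a desk-scale 12,000-cell fixture.
    """
    if full_scale:
        n_cells = 26768

    glial_frac = 0.036
    salivary_frac, sperm_frac = 0.008, 0.004
    other_frac = 3 * 0.004
    neuron_share = 1.0 - glial_frac - salivary_frac - sperm_frac - other_frac

    clusters: list[ClusterSpec] = []
    nm_cycle: list[str] = []
    while len(nm_cycle) < 130:
        nm_cycle.extend(_NEUROMERE_CYCLE)

    ci = 0  # running neuronal-cluster index (for neuromere + birth-order cycling)

    def _birth_order(i: int) -> list[MarkerSpec]:
        ms = []
        if i % 2 == 0:
            ms += [MarkerSpec("pros", 5.0, 0.8), MarkerSpec("dati", 4.0, 0.8)]
        else:
            ms += [MarkerSpec("Imp", 5.0, 0.8), MarkerSpec("mamo", 4.0, 0.8)]
        if i % 3 == 0:
            ms.append(MarkerSpec("br", 4.0, 0.4))
        return ms

    for fan, n_cl, frac_of_neurons in _FAN_PLAN:
        w = _weights(n_cl)
        if fan == "ACh":
            w[:4] *= 1.5  # the four 23B clusters are comparatively large
        w = w / w.sum() * frac_of_neurons * neuron_share
        schedule = _HEMI_SCHEDULE[fan]
        for j in range(n_cl):
            hemi, hemi_markers = (schedule[j] if j < len(schedule) else (None, []))
            nm = nm_cycle[ci]
            markers = (
                list(_STRUCTURAL)
                + [MarkerSpec(m.gene, m.mean_count, m.fraction) for m in _FAN_MARKERS[fan]]
                + [MarkerSpec(g, 6.0, 0.9) for g in hemi_markers]
                + [MarkerSpec(m.gene, m.mean_count, m.fraction) for m in _HOX[nm]]
                + _birth_order(ci)
            )
            if hemi == "23B":
                markers += [MarkerSpec("kn", 10.0, 0.31), MarkerSpec("twz", 10.0, 0.18)]
            clusters.append(
                ClusterSpec(
                    label=f"{fan}_{j:02d}",
                    fraction=w[j],
                    class_="neuronal",
                    fan=fan,
                    hemilineage=hemi,
                    neuromere=nm,
                    markers=markers,
                )
            )
            ci += 1

    # --- FAN-undefined neuronal clusters (4% of neurons) ----------------------
    np_frac, mono_frac, plain_frac = 0.010, 0.015, 0.0075
    np_markers = []
    for k, g in enumerate(_NP_GENES):
        if g == "Orcokinin":
            np_markers.append(MarkerSpec(g, 3000.0, 1.0, n_cells_exact=5))
        elif g == "Lk":
            np_markers.append(MarkerSpec(g, 4000.0, 0.15))
        else:
            np_markers.append(MarkerSpec(g, 4000.0 * 0.87 ** k, 0.15))
    np_markers += [
        MarkerSpec("dimm", 2.0, 0.107),
        MarkerSpec("amon", 5.0),
        MarkerSpec("svr", 5.0),
        MarkerSpec("Phm", 4.0),
        MarkerSpec("Pal2", 4.0),
    ]
    clusters.append(
        ClusterSpec(
            label="NP",
            fraction=np_frac * neuron_share,
            class_="NP",
            fan="none",
            neuromere=nm_cycle[ci],
            markers=np_markers,
            libsize_factor=5277.0 / 2497.0,
        )
    )
    ci += 1

    mono_subtypes = [
        SubtypeSpec("DA", 0.30, [MarkerSpec("DAT", 8.0), MarkerSpec("hth", 5.0), MarkerSpec("mirr", 5.0)]),
        SubtypeSpec("OA/TA", 0.30, [MarkerSpec("Tdc2", 8.0), MarkerSpec("Tbh", 8.0)]),
        SubtypeSpec("HA", 0.20, [MarkerSpec("Hdc", 8.0), MarkerSpec("otp", 5.0), MarkerSpec("Lmx1a", 5.0)]),
        SubtypeSpec("5-HT", 0.20, [MarkerSpec("SerT", 8.0), MarkerSpec("vvl", 5.0), MarkerSpec("ey", 5.0)]),
    ]
    clusters.append(
        ClusterSpec(
            label="monoamine",
            fraction=mono_frac * neuron_share,
            class_="neuronal",
            fan="none",
            neuromere=nm_cycle[ci],
            markers=list(_STRUCTURAL_STRONG) + [MarkerSpec("Vmat", 6.0)],
            subtypes=mono_subtypes,
        )
    )
    ci += 1

    for j in range(2):
        clusters.append(
            ClusterSpec(
                label=f"undef_{j}",
                fraction=plain_frac * neuron_share,
                class_="neuronal",
                fan="none",
                neuromere=nm_cycle[ci],
                markers=list(_STRUCTURAL_STRONG) + _birth_order(ci),
            )
        )
        ci += 1

    # --- glia ----------------------------------------------------------------
    glial_defs = [
        ("glia_astro", 0.010, "astrocyte", [MarkerSpec("alrm", 10.0), MarkerSpec("CG34367", 5.0)], False),
        ("glia_surface", 0.008, "surface", [MarkerSpec("Indy", 8.0), MarkerSpec("Tret1-1", 5.0), MarkerSpec("Vmat", 2.0, 0.3)], False),
        ("glia_cortex", 0.007, "cortex", [MarkerSpec("wrapper", 8.0)], True),
        ("glia_ensheath", 0.006, "ensheathing", [MarkerSpec("Eaat2", 8.0), MarkerSpec("vvl", 4.0)], False),
        ("glia_astro2", 0.005, "astrocyte", [MarkerSpec("alrm", 10.0), MarkerSpec("CG34367", 5.0)], True),
    ]
    for label, frac, subtype, extra, mixed in glial_defs:
        markers = [MarkerSpec("repo", 8.0), MarkerSpec("MRE16", 6.0)] + extra
        if mixed:  # mixed populations: a tail of cells with a neuronal signature
            markers += [MarkerSpec("elav", 3.0, 0.10), MarkerSpec("nSyb", 3.0, 0.10)]
        clusters.append(
            ClusterSpec(
                label=label,
                fraction=frac,
                class_="glial",
                fan="none",
                subtype=subtype,
                markers=markers,
            )
        )

    # --- contaminants + unannotated ------------------------------------------
    clusters.append(
        ClusterSpec(
            "salivary",
            salivary_frac,
            class_="contaminant",
            subtype="salivary",
            markers=[MarkerSpec(g, 20.0, 0.9) for g in _SALIVARY],
        )
    )
    clusters.append(
        ClusterSpec(
            "sperm",
            sperm_frac,
            class_="contaminant",
            subtype="sperm",
            markers=[MarkerSpec(g, 15.0, 0.9) for g in _SPERM],
        )
    )
    for j in range(3):
        clusters.append(
            ClusterSpec(
                f"other_{j}",
                0.004,
                class_="other",
                markers=[MarkerSpec(f"CG{40000 + 3 * j + k}", 8.0) for k in range(3)],
            )
        )

    # normalise tiny rounding drift
    tot = sum(c.fraction for c in clusters)
    for c in clusters:
        c.fraction /= tot

    replicates = [
        ReplicateSpec("rep1", "F", 0.097),
        ReplicateSpec("rep2", "F", 0.338),
        ReplicateSpec("rep3", "M", 0.244),
        ReplicateSpec("rep4", "M", 0.321),
    ]
    return CompositionSpec(
        clusters=clusters,
        n_genes=n_genes,
        replicates=replicates,
        n_cells=n_cells,
        ambient_rate=ambient_rate,
        debris_fraction=debris_fraction,
        seed=seed,
    )
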