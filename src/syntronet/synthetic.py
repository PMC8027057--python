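"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study designs the pipeline targets: a compositional
16S OTU survey (log-normal basis abundances with planted positively-correlated
partner pairs, multinomial read sampling at negative-binomial library depths,
injected contaminant and rare OTUs), tables of flow-sorted single consortia
drawn from a specified P(SRB clade | ANME clade), Poisson ion-count rasters
with spatial 15N-enrichment profiles, and two-channel images with a controlled
signal-overlap fraction. All generators are pure functions of (parameters,
seed): one seed is split deterministically per random source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .imaging import IonCountScene, NATURAL_ABUNDANCE_15N, TwoChannelImage
from .otu import ANME_CLADES, OTHER_CLADE, OtuTable, SRB_CLADES

logger = logging.getLogger(__name__)

_LINEAGE_TEMPLATES = {
    "ANME": "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;{clade};{otu}",
    "SRB": "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;"
    "Desulfobacteraceae;{clade};{otu}",
    "contaminant": "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;"
    "Burkholderiaceae;Ralstonia;{otu}",
}

#: Default genus names cycled through for background ("other") OTUs.
_OTHER_GENERA = ("Anaerolinea", "Desulfobulbus", "Methanococcoides", "Sulfurovum", "JS1")


@dataclass(frozen=True)
class SimOtuConfig:
    """Parameters of the compositional OTU-table generator.

    Desk-scale defaults (60 samples x 300 OTUs) keep the full pipeline fast;
    ``SimOtuConfig.survey_scale()`` returns the full-survey design
    (310 samples x 3052 OTUs). Planted pairs are (i, j, rho_basis) with
    rho_basis in (0, 1] the correlation of the two OTUs' log basis abundances.
    """

    n_samples: int = 60
    n_otus: int = 300
    depth_mean: float = 30_000.0
    depth_dispersion: float = 10.0
    basis_log_mean_sd: float = 1.5
    basis_log_sd: float = 1.0
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    clade_assignments: dict[int, str] = field(default_factory=dict)
    contaminant_ids: tuple[int, ...] = ()
    rare_ids: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_otus < 1:
            raise ParameterError("n_samples and n_otus must be positive")
        if self.depth_mean < 1:
            raise ParameterError("depth_mean must be >= 1")
        for i, j, rho in self.planted_pairs:
            if not (0 <= i < self.n_otus and 0 <= j < self.n_otus):
                raise ParameterError(f"planted pair ({i}, {j}) out of range")
            if i == j:
                raise ParameterError("planted pair indices must be distinct")
            if not 0.0 < rho <= 1.0:
                raise ParameterError(f"rho_basis must be in (0, 1], got {rho}")
        for ids, name in ((self.contaminant_ids, "contaminant"), (self.rare_ids, "rare")):
            for i in ids:
                if not 0 <= i < self.n_otus:
                    raise ParameterError(f"{name} OTU index {i} out of range")

    @classmethod
    def survey_scale(cls, **overrides) -> "SimOtuConfig":
        """Full-survey design: 310 samples x 3052 OTUs."""
        base = dict(n_samples=310, n_otus=3052)
        base.update(overrides)
        return cls(**base)


def _planted_correlation_matrix(config: SimOtuConfig) -> np.ndarray:
    C = np.eye(config.n_otus)
    for i, j, rho in config.planted_pairs:
        C[i, j] = C[j, i] = rho
    return C


def basis_log_abundances(config: SimOtuConfig) -> np.ndarray:
    """Latent log basis abundances (n_samples x n_otus) implied by the config.

    Drawn from a multivariate normal whose correlation is the identity except
    at planted pairs. Exposed so recovery studies can compare inference against
    the generative truth.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_basis, _, _ = (np.random.default_rng(s) for s in ss.spawn(3))
    C = _planted_correlation_matrix(config)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        raise ParameterError("planted correlation matrix is not positive definite")
    mu = rng_basis.normal(0.0, config.basis_log_mean_sd, config.n_otus)
    z = rng_basis.standard_normal((config.n_samples, config.n_otus)) @ L.T
    return mu + config.basis_log_sd * z


def gen_otu_table(config: SimOtuConfig) -> OtuTable:
    """Generate a compositional OTU count table with planted structure.

    Per sample: exponentiate the log basis abundances, normalize to fractions,
    draw a negative-binomial library depth, then draw counts multinomially.
    Contaminant OTUs receive a recognizable reagent-genus lineage; rare OTUs
    get tiny basis fractions and are capped below 10 reads per library (capped
    excess moves to the sample's most abundant non-rare OTU so library depths
    are conserved exactly).
    """
    ss = np.random.SeedSequence(config.seed)
    _, rng_depth, rng_counts = (np.random.default_rng(s) for s in ss.spawn(3))
    log_basis = basis_log_abundances(config)
    basis = np.exp(log_basis)
    rare = np.asarray(config.rare_ids, dtype=int)
    if rare.size:
        others = basis.sum(axis=1, keepdims=True) - basis[:, rare].sum(axis=1, keepdims=True)
        basis[:, rare] = others * (2.0 / config.depth_mean)
    fractions = basis / basis.sum(axis=1, keepdims=True)

    k = config.depth_dispersion
    p = k / (k + config.depth_mean)
    depths = np.maximum(rng_depth.negative_binomial(k, p, config.n_samples), 1)

    counts = np.empty((config.n_samples, config.n_otus), dtype=np.int64)
    for s in range(config.n_samples):
        counts[s] = rng_counts.multinomial(depths[s], fractions[s])
    if rare.size:
        non_rare = np.setdiff1d(np.arange(config.n_otus), rare)
        for s in range(config.n_samples):
            excess = counts[s, rare] - 9
            excess[excess < 0] = 0
            if excess.any():
                counts[s, rare] -= excess
                top = non_rare[np.argmax(counts[s, non_rare])]
                counts[s, top] += excess.sum()

    otu_ids, lineages, clades = [], [], []
    contaminants = set(int(i) for i in config.contaminant_ids)
    for j in range(config.n_otus):
        oid = f"OTU_{j:04d}"
        otu_ids.append(oid)
        clade = config.clade_assignments.get(j, OTHER_CLADE)
        clades.append(clade)
        if j in contaminants:
            lineages.append(_LINEAGE_TEMPLATES["contaminant"].format(otu=oid))
        elif clade in ANME_CLADES:
            lineages.append(_LINEAGE_TEMPLATES["ANME"].format(clade=clade, otu=oid))
        elif clade in SRB_CLADES:
            lineages.append(_LINEAGE_TEMPLATES["SRB"].format(clade=clade, otu=oid))
        else:
            genus = _OTHER_GENERA[j % len(_OTHER_GENERA)]
            lineages.append(
                f"Bacteria;Phylum{j % 7};Class{j % 5};Order{j % 4};Family{j % 3};"
                f"{genus};{oid}"
            )
    return OtuTable(
        counts=counts,
        sample_ids=tuple(f"S{s:03d}" for s in range(config.n_samples)),
        otu_ids=tuple(otu_ids),
        lineage=tuple(lineages),
        clade=tuple(clades),
    )


def partnership_demo_config(seed: int = 0, n_samples: int = 300, n_otus: int = 60) -> SimOtuConfig:
    """Desk-scale end-to-end scenario with a planted ANME-2b--SEEP-SRB1g module.

    One ANME-2b OTU and five SEEP-SRB1g OTUs form a fully co-occurring module
    (all pairwise rho_basis = 0.9), giving exactly five planted ANME-SRB
    partner pairs. Three weak (rho = 0.3) background correlations attach the
    module to unrelated OTUs, emulating the connected structure of a real seep
    network, so the module emerges as a nested cohesive block rather than an
    isolated component.
    """
    import itertools

    module = list(range(6))
    pairs = [(i, j, 0.9) for i, j in itertools.combinations(module, 2)]
    pairs += [(1, 6, 0.3), (2, 7, 0.3), (3, 8, 0.3)]
    clades = {0: "ANME-2b", **{i: "SEEP-SRB1g" for i in range(1, 6)}}
    return SimOtuConfig(
        n_samples=n_samples,
        n_otus=n_otus,
        planted_pairs=tuple(pairs),
        clade_assignments=clades,
        seed=seed,
    )


#: The five planted ANME-SRB partner pairs of :func:`partnership_demo_config`.
DEMO_PLANTED_CROSS_PAIRS = frozenset(
    (f"OTU_{0:04d}", f"OTU_{j:04d}") for j in range(1, 6)
)


# ---------------------------------------------------------------------------
# Sorted consortia


@dataclass(frozen=True)
class ConsortiumSortTable:
    """One row per flow-sorted consortium: (sort_id, anme_clade, srb_clade)."""

    sort_id: tuple[str, ...]
    anme_clade: tuple[str, ...]
    srb_clade: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.sort_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sort_id": list(self.sort_id),
                "anme_clade": list(self.anme_clade),
                "srb_clade": list(self.srb_clade),
            }
        )


DEFAULT_SORT_ANME = ("ANME-1", "ANME-2a", "ANME-2b", "ANME-2c")
DEFAULT_SORT_SRB = ("SEEP-SRB1a", "SEEP-SRB1g", "SEEP-SRB2")


def gen_sorted_consortia(
    spec_matrix,
    anme_marginal,
    n_sorts: int,
    seed=0,
    anme_clades=None,
    srb_clades=None,
) -> ConsortiumSortTable:
    """Draw sorted consortia: ANME clade from the marginal, SRB from P(srb|anme).

    ``spec_matrix`` rows must be probability vectors (one per ANME clade).
    """
    spec_matrix = np.asarray(spec_matrix, dtype=float)
    anme_marginal = np.asarray(anme_marginal, dtype=float)
    anme_clades = tuple(anme_clades) if anme_clades is not None else DEFAULT_SORT_ANME[: spec_matrix.shape[0]]
    srb_clades = tuple(srb_clades) if srb_clades is not None else DEFAULT_SORT_SRB[: spec_matrix.shape[1]]
    if n_sorts < 1:
        raise ParameterError("n_sorts must be >= 1")
    if spec_matrix.ndim != 2 or spec_matrix.shape != (len(anme_clades), len(srb_clades)):
        raise ParameterError("spec_matrix shape must match clade label counts")
    if np.any(spec_matrix < 0) or not np.allclose(spec_matrix.sum(axis=1), 1.0, atol=1e-8):
        raise ParameterError("spec_matrix rows must be probability vectors")
    if np.any(anme_marginal < 0) or not np.isclose(anme_marginal.sum(), 1.0, atol=1e-8):
        raise ParameterError("anme_marginal must be a probability vector")
    rng = np.random.default_rng(seed)
    a_idx = rng.choice(len(anme_clades), size=n_sorts, p=anme_marginal)
    srb = [
        srb_clades[rng.choice(len(srb_clades), p=spec_matrix[a])] for a in a_idx
    ]
    return ConsortiumSortTable(
        sort_id=tuple(f"sort_{i:03d}" for i in range(n_sorts)),
        anme_clade=tuple(anme_clades[a] for a in a_idx),
        srb_clade=tuple(srb),
    )


# ---------------------------------------------------------------------------
# nanoSIMS scenes


@dataclass(frozen=True)
class RoiSpec:
    """Circular single-cell ROI: taxon label, centre (um) and radius (um)."""

    taxon: str
    x_um: float
    y_um: float
    radius_um: float


def uniform_profile(atom_fraction: float = NATURAL_ABUNDANCE_15N):
    """Enrichment profile constant over the consortium."""
    if not 0.0 <= atom_fraction < 1.0:
        raise ParameterError("atom fraction must be in [0, 1)")
    return lambda depth_um: np.full_like(np.asarray(depth_um, dtype=float), atom_fraction)


def linear_gradient_profile(surface_fraction: float, interior_fraction: float, ramp_um: float):
    """Enrichment rising (or falling) linearly from the boundary over ``ramp_um``."""

    def profile(depth_um):
        depth_um = np.asarray(depth_um, dtype=float)
        t = np.clip(depth_um / ramp_um, 0.0, 1.0)
        return surface_fraction + (interior_fraction - surface_fraction) * t

    return profile


def gen_nanosims_scene(
    radius_um: float,
    pixel_size_um: float,
    roi_spec: list[RoiSpec],
    enrichment_profile,
    counts_per_pixel: float,
    seed=0,
) -> IonCountScene:
    """Poisson ion-count raster of a disk-shaped consortium with labeled ROIs.

    The true 15N atom fraction at each pixel is ``enrichment_profile`` evaluated
    at the pixel's distance from the consortium boundary; 15N12C- and 12C14N-
    counts are independent Poisson draws whose expected ratio equals that
    fraction. ROIs must lie inside the disk and be pairwise disjoint.
    """
    if radius_um <= 0 or pixel_size_um <= 0 or counts_per_pixel <= 0:
        raise ParameterError("radius, pixel size and counts_per_pixel must be > 0")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(2.0 * radius_um / pixel_size_um)) + 4
    yy, xx = np.mgrid[0:n, 0:n]
    cx = cy = n * pixel_size_um / 2.0
    px_x = (xx + 0.5) * pixel_size_um
    px_y = (yy + 0.5) * pixel_size_um
    r = np.sqrt((px_x - cx) ** 2 + (px_y - cy) ** 2)
    mask = r <= radius_um
    depth = np.maximum(radius_um - r, 0.0)  # distance from the disk boundary

    frac = np.clip(np.asarray(enrichment_profile(depth), dtype=float), 0.0, 1.0 - 1e-12)
    lam15 = counts_per_pixel * frac
    lam14 = counts_per_pixel * (1.0 - frac)
    c15 = np.where(mask, rng.poisson(lam15), 0)
    c14 = np.where(mask, rng.poisson(lam14), 0)

    labels = np.zeros((n, n), dtype=np.int64)
    meta = []
    for idx, roi in enumerate(roi_spec, start=1):
        d_center = np.sqrt((roi.x_um - cx) ** 2 + (roi.y_um - cy) ** 2)
        if d_center + roi.radius_um > radius_um:
            raise GenerationError(f"ROI {idx} extends outside the consortium disk")
        pix = (px_x - roi.x_um) ** 2 + (px_y - roi.y_um) ** 2 <= roi.radius_um**2
        if not pix.any():
            raise GenerationError(f"ROI {idx} covers no pixels at this pixel size")
        if np.any(labels[pix] != 0):
            raise GenerationError(f"ROI {idx} overlaps a previous ROI")
        labels[pix] = idx
        meta.append(
            {
                "roi_id": idx,
                "taxon": roi.taxon,
                "centroid_x_um": float(px_x[pix].mean()),
                "centroid_y_um": float(px_y[pix].mean()),
            }
        )
    return IonCountScene(
        c14=c14.astype(np.int64),
        c15=c15.astype(np.int64),
        pixel_size_um=pixel_size_um,
        mask=mask,
        roi_labels=labels,
        roi_meta=pd.DataFrame(meta, columns=["roi_id", "taxon", "centroid_x_um", "centroid_y_um"]),
    )


# ---------------------------------------------------------------------------
# Two-channel images


def gen_two_channel_image(
    shape: tuple[int, int] = (128, 128),
    overlap_fraction: float = 1.0,
    intensity: float = 100.0,
    noise_sd: float = 0.0,
    b_only_fraction: float = 0.0,
    seed=0,
) -> TwoChannelImage:
    """Two-channel image where B covers exactly ``overlap_fraction`` of A's mass.

    Channel A is a centred uniform-intensity rectangle; channel B lights the
    first round(alpha * nA) pixels of A's support (raster order) plus an
    optional disjoint B-only rectangle sized as a fraction of A's support.
    Optional additive Gaussian noise is clipped at zero.
    """
    alpha = overlap_fraction
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("overlap_fraction must be in [0, 1]")
    h, w = shape
    a = np.zeros(shape, dtype=float)
    b = np.zeros(shape, dtype=float)
    r0, r1 = h // 4, h // 2
    c0, c1 = w // 4, 3 * w // 4
    a[r0:r1, c0:c1] = intensity
    support = np.argwhere(a > 0)
    n_a = len(support)
    k = int(round(alpha * n_a))
    for i, j in support[:k]:
        b[i, j] = intensity
    if b_only_fraction > 0:
        n_b_only = int(round(b_only_fraction * n_a))
        rb0 = 3 * h // 4
        flat = [(i, j) for i in range(rb0, h) for j in range(c0, c1)]
        for i, j in flat[:n_b_only]:
            b[i, j] = intensity
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = np.clip(a + rng.normal(0.0, noise_sd, shape), 0.0, None)
        b = np.clip(b + rng.normal(0.0, noise_sd, shape), 0.0, None)
    return TwoChannelImage(a=a, b=b)
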