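"""Synthetic paired bulk + spot cohorts with a known embedding-expression map.

Each slide carries an L-dimensional latent "morphology" field that varies
smoothly in space (a low-frequency cosine mixture plus a slide-level
offset).  Patch embeddings are an affine image of the latent plus optional
Gaussian noise; per-patch/spot mean log-expression is a second affine image
of the same latent, so expression is exactly predictable from embeddings in
the noiseless limit.  Counts, when requested, are Poisson draws with a
softmax-normalized gene composition, giving Visium-like sparsity; bulk
counts are the sum of patch-level counts and pseudo-bulk is reproducible
from the spot counts.  Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expr_prep import ExpressionMatrix

PATCH_SIZE = 256


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults are the desk-scale bi-scale cohort used throughout the tests:
    40 bulk slides of 30 patches and 10 spatial slides of 50 spots, with a
    4-dim latent field, 16-dim embeddings and a 20-gene panel.
    ``count_depth=None`` generates noiseless targets (exact mean
    log-expression, no count sampling); a positive depth draws Poisson
    counts with that expected per-spot library size.
    """

    n_patients: int = 40            # bulk slides (one slide per patient)
    patches_per_slide: int = 30
    n_spot_slides: int = 10
    spots_per_slide: int = 50
    n_genes: int = 20
    embed_dim: int = 16
    latent_dim: int = 4
    noise_sd: float = 0.0           # embedding noise
    count_depth: float | None = None  # expected library size; None = noiseless
    overdispersion: float = 0.0     # NB dispersion; 0 = Poisson
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients", "patches_per_slide", "n_spot_slides",
                     "spots_per_slide", "n_genes", "embed_dim", "latent_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.latent_dim > self.embed_dim:
            raise ValueError("latent_dim must not exceed embed_dim")
        if self.noise_sd < 0 or self.overdispersion < 0:
            raise ValueError("noise_sd and overdispersion must be non-negative")
        if self.count_depth is not None and self.count_depth <= 0:
            raise ValueError("count_depth must be positive when set")


@dataclass
class SynthTruth:
    """Ground-truth generative maps, sufficient for oracle predictions."""

    embed_weights: np.ndarray   # d x L
    embed_bias: np.ndarray      # d
    expr_weights: np.ndarray    # G x L
    expr_bias: np.ndarray       # G
    gene_ids: list[str]
    bulk_latents: dict[str, np.ndarray]   # slide_id -> n_patches x L
    spot_latents: dict[str, np.ndarray]   # slide_id -> n_spots x L

    def expected_log_expression(self, latents: np.ndarray) -> np.ndarray:
        """Oracle mean log-expression (items x G) for given latents."""
        return latents @ self.expr_weights.T + self.expr_bias


@dataclass
class BulkSample:
    slide_id: str
    patient_id: str
    embeddings: np.ndarray      # n_patches x d
    coords: np.ndarray          # n_patches x 2 pixel origins (x, y)
    counts: np.ndarray | None   # per-gene bulk counts (None in noiseless mode)
    z_global: np.ndarray        # G target (log2 scale)


@dataclass
class SpotSample:
    slide_id: str
    patient_id: str
    embeddings: np.ndarray      # n_spots x d
    coords: np.ndarray          # n_spots x 2 pixel centers (x, y)
    counts: np.ndarray | None   # G x n_spots spot counts
    z_local: np.ndarray         # n_spots x G targets (log2 scale)
    z_global: np.ndarray        # G pseudo-bulk target (log2 scale)


@dataclass
class Cohort:
    bulk: list[BulkSample]
    spots: list[SpotSample]
    truth: SynthTruth
    config: SynthConfig = field(default=None)  # type: ignore[assignment]


def _latent_field(rng: np.random.Generator, coords: np.ndarray, L: int) -> np.ndarray:
    """Smooth spatial latent: per-dim mixture of 3 low-frequency cosines over
    pixel coordinates, plus a slide-level N(0,1) offset per dimension."""
    xy = coords.astype(float) / (PATCH_SIZE * 8.0)  # a few periods per slide
    lat = np.empty((coords.shape[0], L))
    offset = rng.normal(0.0, 1.0, size=L)
    for l in range(L):
        freqs = rng.uniform(0.2, 1.0, size=(3, 2))
        phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        amps = rng.uniform(0.3, 1.0, size=3)
        lat[:, l] = offset[l] + sum(
            amps[k] * np.cos(2.0 * np.pi * (xy @ freqs[k]) + phases[k])
            for k in range(3)
        )
    return lat


def _grid_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    grid = np.stack([xs.ravel(), ys.ravel()], axis=1)[:n]
    return grid * PATCH_SIZE


def _draw_counts(rng: np.random.Generator, mu_log: np.ndarray, depth: float,
                 overdispersion: float) -> np.ndarray:
    """Counts for one item: Poisson(depth * softmax over genes of mu_log),
    optionally Gamma-mixed for negative-binomial overdispersion."""
    w = np.exp(mu_log - mu_log.max())
    p = w / w.sum()
    lam = depth * p
    if overdispersion > 0:
        lam = rng.gamma(1.0 / overdispersion, overdispersion * lam)
    return rng.poisson(lam).astype(float)


def generate_cohort(cfg: SynthConfig) -> Cohort:
    """Generate paired bulk and spatial samples plus the generative truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    d, L, G = cfg.embed_dim, cfg.latent_dim, cfg.n_genes
    gene_ids = [f"g{i:04d}" for i in range(G)]

    # orthonormal embedding map: latents stay recoverable at any d >= L and
    # embedding entries keep the O(1) scale typical of encoder outputs
    E = np.linalg.qr(rng.normal(size=(d, L)))[0]
    e0 = rng.normal(0.0, 0.1, size=d)
    M = rng.normal(0.0, 1.0, size=(G, L)) / np.sqrt(L)
    m0 = rng.normal(3.0, 0.5, size=G)  # log2-scale baseline expression

    truth = SynthTruth(E, e0, M, m0, gene_ids, {}, {})
    bulk_samples: list[BulkSample] = []
    spot_samples: list[SpotSample] = []

    for p_idx in range(cfg.n_patients):
        slide_id = f"bulk{p_idx:03d}"
        coords = _grid_coords(cfg.patches_per_slide, rng)
        lat = _latent_field(rng, coords, L)
        emb = lat @ E.T + e0
        if cfg.noise_sd > 0:
            emb = emb + rng.normal(0.0, cfg.noise_sd, size=emb.shape)
        mu = truth.expected_log_expression(lat)  # n x G
        if cfg.count_depth is None:
            counts, z_global = None, mu.mean(axis=0)
        else:
            counts = np.zeros(G)
            for i in range(mu.shape[0]):
                counts += _draw_counts(rng, mu[i], cfg.count_depth, cfg.overdispersion)
            s = counts.sum()
            cpm = counts / s * 1e6 if s > 0 else counts
            z_global = np.log2(cpm + 1.0)
        truth.bulk_latents[slide_id] = lat
        bulk_samples.append(BulkSample(slide_id, f"P{p_idx:03d}", emb, coords,
                                       counts, z_global))

    for s_idx in range(cfg.n_spot_slides):
        slide_id = f"spot{s_idx:03d}"
        patient_id = f"S{s_idx:03d}"
        centers = _grid_coords(cfg.spots_per_slide, rng) + PATCH_SIZE // 2
        lat = _latent_field(rng, centers, L)
        emb = lat @ E.T + e0
        if cfg.noise_sd > 0:
            emb = emb + rng.normal(0.0, cfg.noise_sd, size=emb.shape)
        mu = truth.expected_log_expression(lat)  # n_spots x G
        if cfg.count_depth is None:
            counts = None
            z_local = mu
            z_global = mu.mean(axis=0)
        else:
            counts = np.zeros((G, cfg.spots_per_slide))
            for i in range(cfg.spots_per_slide):
                counts[:, i] = _draw_counts(rng, mu[i], cfg.count_depth,
                                            cfg.overdispersion)
            colsum = counts.sum(axis=0)
            safe = np.where(colsum == 0, 1.0, colsum)
            z_local = np.log2((counts / safe * 1e6).T + 1.0)
            total = counts.sum(axis=1)
            pb = total / total.sum() * 1e6 if total.sum() > 0 else total
            z_global = np.log2(pb + 1.0)
        truth.spot_latents[slide_id] = lat
        spot_samples.append(SpotSample(slide_id, patient_id, emb, centers,
                                       counts, z_local, z_global))

    return Cohort(bulk_samples, spot_samples, truth, cfg)


def spot_counts_matrix(sample: SpotSample, gene_ids: list[str]) -> ExpressionMatrix:
    """Wrap one spatial sample's counts as a gene x spot ExpressionMatrix."""
    if sample.counts is None:
        raise ValueError("sample was generated in noiseless mode (no counts)")
    barcodes = [f"{sample.slide_id}-spot{i:04d}" for i in range(sample.counts.shape[1])]
    return ExpressionMatrix(sample.counts, list(gene_ids), barcodes, "raw_counts")


# ---------------------------------------------------------------------------
# Tissue-image fixtures for the WSI tiling path
# ---------------------------------------------------------------------------

def generate_tissue_image(
    width: int = 1024,
    height: int = 1024,
    n_blobs: int = 4,
    seed: int = 0,
    blob_color: tuple[int, int, int] = (190, 60, 150),
) -> tuple[np.ndarray, np.ndarray]:
    """A white background with colored elliptical "tissue" blobs.

    Returns (rgb image HxWx3 uint8, boolean tissue mask HxW).  Per-tile true
    coverage is computable from the mask, which makes the image a ground
    truth fixture for tile filtering.
    """
    rng = np.random.default_rng(seed)
    img = np.full((height, width, 3), 255, dtype=np.uint8)
    mask = np.zeros((height, width), dtype=bool)
    yy, xx = np.mgrid[0:height, 0:width]
    for _ in range(n_blobs):
        cx = rng.uniform(0.15 * width, 0.85 * width)
        cy = rng.uniform(0.15 * height, 0.85 * height)
        rx = rng.uniform(0.08, 0.25) * width
        ry = rng.uniform(0.08, 0.25) * height
        theta = rng.uniform(0, np.pi)
        dx, dy = xx - cx, yy - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask |= (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    img[mask] = blob_color
    return img, mask
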