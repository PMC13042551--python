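"""Synthetic spatial transcriptomics fixtures with known ground truth.

Emulates the structure the model exploits in real tissue: spots on a 2-D
lattice partitioned into contiguous spatial domains (Voronoi regions of
random seed points), domain-specific marker-gene programs on top of
negative-binomial counts with Bernoulli dropout, and per-spot image patches
whose mean color correlates with domain identity.

Ground-truth labels are stored on the returned dataset but are never read by
any training code — they exist solely for evaluation.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .data_io import SpatialDataset

__all__ = ["SynthConfig", "generate"]

LATTICE_SPACING = 100.0  # pixels between adjacent lattice spots


@dataclass
class SynthConfig:
    """Generator settings.

    Defaults describe a small but clearly structured tissue: a 30 × 30 spot
    lattice with 4 domains, 200 genes of which 10 per domain are markers with
    a natural-log fold change of 2 (≈ 7.4×), 30% technical dropout, moderate
    negative-binomial overdispersion, and patch colors mixed 80% of the way
    from neutral gray toward a domain-specific hue.
    """

    grid_rows: int = 30
    grid_cols: int = 30
    n_domains: int = 4
    n_genes: int = 200
    markers_per_domain: int = 10
    marker_log_fold: float = 2.0
    dropout_rate: float = 0.3
    nb_dispersion: float = 2.0
    patch_size: int = 16
    patch_color_separation: float = 0.8
    patch_noise_sd: float = 12.0
    base_mean: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_domains < 2:
            raise ValueError("n_domains must be ≥ 2")
        if self.markers_per_domain * self.n_domains > self.n_genes:
            raise ValueError("markers_per_domain × n_domains must be ≤ n_genes")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.patch_color_separation <= 1:
            raise ValueError("patch_color_separation must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.marker_log_fold < 0:
            raise ValueError("marker_log_fold must be ≥ 0")


def _voronoi_labels(rows: int, cols: int, c: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous domain labels on the lattice via Voronoi regions of c seed
    points; reseeds until every domain is non-empty and 4-connected."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    for _ in range(100):
        seeds = grid[rng.choice(rows * cols, size=c, replace=False)]
        d2 = ((grid[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)  # argmin ties → lowest seed index
        field = labels.reshape(rows, cols)
        ok = True
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for k in range(c):
            mask = field == k
            if not mask.any():
                ok = False
                break
            _, n_comp = scipy.ndimage.label(mask, structure=structure)
            if n_comp != 1:
                ok = False
                break
        if ok:
            return labels
    raise RuntimeError("could not place contiguous Voronoi domains")


def _domain_palette(c: int) -> np.ndarray:
    """c maximally distinct saturated RGB colors (evenly spaced hues)."""
    return np.array(
        [colorsys.hsv_to_rgb(k / c, 1.0, 1.0) for k in range(c)]
    ) * 255.0


def domain_mean_matrix(config: SynthConfig) -> np.ndarray:
    """(n_domains, n_genes) negative-binomial mean matrix before dropout.

    Gene g is a marker of domain k when g ∈ [k·mpd, (k+1)·mpd); its mean in
    that domain is the base mean times exp(marker_log_fold).
    """
    means = np.full((config.n_domains, config.n_genes), config.base_mean)
    mpd = config.markers_per_domain
    for k in range(config.n_domains):
        means[k, k * mpd:(k + 1) * mpd] *= np.exp(config.marker_log_fold)
    return means


def generate(config: SynthConfig) -> SpatialDataset:
    """Draw one dataset.  Identical config (incl. seed) ⇒ bit-identical output."""
    rng = np.random.default_rng(config.seed)
    rows, cols, c = config.grid_rows, config.grid_cols, config.n_domains
    n = rows * cols

    labels = _voronoi_labels(rows, cols, c, rng)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    S = np.stack([cc.ravel() * LATTICE_SPACING, rr.ravel() * LATTICE_SPACING], axis=1)

    # negative-binomial counts via the gamma–Poisson mixture:
    # mean μ, dispersion θ ⇒ variance μ + μ²/θ
    mu = domain_mean_matrix(config)[labels]  # (n, n_genes)
    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.float64)
    if config.dropout_rate > 0:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts *= keep

    palette = _domain_palette(c)
    gray = np.full(3, 128.0)
    sep = config.patch_color_separation
    mean_colors = gray * (1 - sep) + palette * sep  # (c, 3)
    ps = config.patch_size
    noise = rng.normal(0.0, config.patch_noise_sd, size=(n, ps, ps, 3))
    patches = mean_colors[labels][:, None, None, :] + noise
    patches = np.clip(patches, 0, 255).astype(np.uint8)

    return SpatialDataset(
        X=counts,
        S=S,
        gene_names=[f"gene_{g}" for g in range(config.n_genes)],
        spot_ids=[f"spot_{i}" for i in range(n)],
        patches=patches,
        labels=labels,
        uns={"synthetic": True, "n_domains": c, "seed": config.seed},
    )
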