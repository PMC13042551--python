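"""Reading, writing and preprocessing of spatially resolved expression data.

The universal in-memory container is :class:`SpatialDataset`: a spot × gene
expression matrix, per-spot pixel coordinates, and optionally per-spot
histology patches and ground-truth labels.  Supported on-disk formats are
AnnData ``.h5ad``, the 10x-style Matrix Market triplet, and plain CSV.

Coordinate convention: 0-based pixel coordinates ordered ``(x, y)`` =
(image column, image row).  The spatial k-nearest-neighbor graph is built in
these same units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "SpatialDataset",
    "read_dataset",
    "write_dataset",
    "read_image",
    "normalize_expression",
    "select_hvgs",
    "extract_patches",
]

DEFAULT_TARGET_SUM = 1e4
# default patch sizes per platform resolution (pixels)
PATCH_SIZES = {"visium": 16, "cosmx": 60, "merfish": 40}


@dataclass
class SpatialDataset:
    """Spot-level expression with spatial coordinates.

    Attributes
    ----------
    X : (n_spots, n_genes) float array
        Expression matrix; raw counts after reading, log-normalized after
        :func:`normalize_expression`.
    S : (n_spots, 2) float array
        Pixel coordinates, (x=column, y=row), 0-based.
    gene_names, spot_ids : lists of str
    patches : optional (n_spots, h, w, 3) uint8 array
    labels : optional (n_spots,) array of categorical labels
    """

    X: np.ndarray
    S: np.ndarray
    gene_names: list[str]
    spot_ids: list[str]
    patches: np.ndarray | None = None
    labels: np.ndarray | None = None
    uns: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if scipy.sparse.issparse(self.X):
            self.X = np.asarray(self.X.todense(), dtype=np.float64)
        self.S = np.asarray(self.S, dtype=np.float64)
        n = self.X.shape[0]
        if self.S.shape != (n, 2):
            raise ValueError(
                f"coordinate table has {self.S.shape[0]} rows but the "
                f"expression matrix has {n} spots"
            )
        if len(self.gene_names) != self.X.shape[1]:
            raise ValueError("gene_names length does not match n_genes")
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length does not match n_spots")
        if len(set(self.spot_ids)) != n:
            raise ValueError("spot_ids must be unique")
        if self.patches is not None and self.patches.shape[0] != n:
            raise ValueError("patches row count does not match n_spots")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError("labels length does not match n_spots")

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    # ---- AnnData bridge ----------------------------------------------
    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.X.copy(),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.obsm["spatial"] = self.S.copy()
        if self.patches is not None:
            n, h, w, _ = self.patches.shape
            adata.obsm["patches"] = self.patches.reshape(n, -1).astype(np.uint8)
            adata.uns["patch_shape"] = [int(h), int(w), 3]
        if self.labels is not None:
            adata.obs["label"] = pd.Categorical(np.asarray(self.labels).astype(str))
        for k, v in self.uns.items():
            adata.uns[k] = v
        return adata

    @classmethod
    def from_anndata(cls, adata: ad.AnnData, label_key: str = "label") -> "SpatialDataset":
        X = adata.X
        if scipy.sparse.issparse(X):
            X = np.asarray(X.todense())
        patches = None
        if "patches" in adata.obsm:
            h, w, c = (int(v) for v in adata.uns["patch_shape"])
            patches = np.asarray(adata.obsm["patches"], dtype=np.uint8).reshape(-1, h, w, c)
        labels = None
        if label_key in adata.obs:
            labels = np.asarray(adata.obs[label_key])
        uns = {k: v for k, v in adata.uns.items() if k != "patch_shape"}
        return cls(
            X=np.asarray(X, dtype=np.float64),
            S=np.asarray(adata.obsm["spatial"], dtype=np.float64),
            gene_names=list(adata.var_names),
            spot_ids=list(adata.obs_names),
            patches=patches,
            labels=labels,
            uns=uns,
        )


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required file not found: {path}")
    return path


def read_dataset(path: str | os.PathLike, format: str = "h5ad",
                 coords_path: str | os.PathLike | None = None) -> SpatialDataset:
    """Read a spatial dataset from disk.  ``X`` holds raw counts; call
    :func:`normalize_expression` separately.

    Formats
    -------
    h5ad
        AnnData container (X, obsm["spatial"], optional obs["label"],
        obsm["patches"]).
    mtx_triplet
        Directory with ``matrix.mtx`` (genes × spots), ``features.tsv``,
        ``barcodes.tsv`` and ``coordinates.csv`` (columns x, y).
    csv
        Expression CSV (spots × genes, header = gene names, index = spot
        ids); coordinates in ``coords_path`` or a sibling
        ``coordinates.csv``.
    """
    path = Path(path)
    if format == "h5ad":
        _require(path)
        return SpatialDataset.from_anndata(ad.read_h5ad(path))
    if format == "mtx_triplet":
        mtx = _require(path / "matrix.mtx")
        feats = _require(path / "features.tsv")
        bars = _require(path / "barcodes.tsv")
        coords = _require(path / "coordinates.csv")
        X = np.asarray(scipy.io.mmread(mtx).todense()).T  # genes × spots on disk
        gene_names = pd.read_csv(feats, sep="\t", header=None)[0].astype(str).tolist()
        spot_ids = pd.read_csv(bars, sep="\t", header=None)[0].astype(str).tolist()
        cdf = pd.read_csv(coords, index_col=0)
        S = cdf[["x", "y"]].to_numpy(dtype=np.float64)
        if S.shape[0] != X.shape[0]:
            raise ValueError(
                f"coordinates file has {S.shape[0]} rows but matrix has "
                f"{X.shape[0]} spots"
            )
        labels = cdf["label"].to_numpy() if "label" in cdf.columns else None
        return SpatialDataset(X=X, S=S, gene_names=gene_names, spot_ids=spot_ids,
                              labels=labels)
    if format == "csv":
        _require(path)
        coords = Path(coords_path) if coords_path else path.parent / "coordinates.csv"
        _require(coords)
        xdf = pd.read_csv(path, index_col=0)
        cdf = pd.read_csv(coords, index_col=0)
        S = cdf[["x", "y"]].to_numpy(dtype=np.float64)
        if S.shape[0] != xdf.shape[0]:
            raise ValueError(
                f"coordinates file has {S.shape[0]} rows but matrix has "
                f"{xdf.shape[0]} spots"
            )
        labels = cdf["label"].to_numpy() if "label" in cdf.columns else None
        return SpatialDataset(
            X=xdf.to_numpy(dtype=np.float64),
            S=S,
            gene_names=[str(g) for g in xdf.columns],
            spot_ids=[str(s) for s in xdf.index],
            labels=labels,
        )
    raise ValueError(f"unknown format: {format!r}")


def write_dataset(ds: SpatialDataset, path: str | os.PathLike,
                  format: str = "h5ad") -> None:
    """Write a dataset in any of the formats :func:`read_dataset` reads.

    Patches are preserved only by the h5ad container.
    """
    path = Path(path)
    if format == "h5ad":
        ds.to_anndata().write_h5ad(path)
        return
    cdf = pd.DataFrame({"x": ds.S[:, 0], "y": ds.S[:, 1]},
                       index=pd.Index(ds.spot_ids, name="spot_id"))
    if ds.labels is not None:
        cdf["label"] = np.asarray(ds.labels)
    if format == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.csr_matrix(ds.X.T))
        pd.Series(ds.gene_names).to_csv(path / "features.tsv", sep="\t",
                                        header=False, index=False)
        pd.Series(ds.spot_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
        cdf.to_csv(path / "coordinates.csv")
        return
    if format == "csv":
        pd.DataFrame(ds.X, index=pd.Index(ds.spot_ids, name="spot_id"),
                     columns=ds.gene_names).to_csv(path)
        cdf.to_csv(path.parent / "coordinates.csv")
        return
    raise ValueError(f"unknown format: {format!r}")


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Load a histology image (PNG/TIFF/JPEG) as an h × w × 3 uint8 array."""
    from PIL import Image

    img = Image.open(_require(Path(path))).convert("RGB")
    return np.asarray(img, dtype=np.uint8)


def normalize_expression(X_raw: np.ndarray, target_sum: float = DEFAULT_TARGET_SUM,
                         library_scale: bool = True) -> np.ndarray:
    """Library-size scaling to ``target_sum`` per spot followed by log1p.

    Set ``library_scale=False`` for a bare log transform.  All-zero spots
    stay all-zero.
    """
    X = np.asarray(X_raw, dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("expression counts must be non-negative")
    if library_scale:
        lib = X.sum(axis=1, keepdims=True)
        scale = np.divide(target_sum, lib, out=np.ones_like(lib), where=lib > 0)
        X = X * scale
    return np.log1p(X)


def select_hvgs(X_raw: np.ndarray, n_top: int = 3000) -> np.ndarray:
    """Rank genes by normalized dispersion and return the top ``n_top`` indices.

    Seurat-flavor statistic: expression is library-size normalized and
    log-transformed, then exponentiated back (expm1); per-gene dispersion is
    variance/mean; genes are cut into 20 equal-width mean bins and the
    dispersion is z-scored within its bin.  Bins with fewer than two genes
    (or zero spread) fall back to the z-score of dispersion across all
    genes, so a clearly dominant gene is never silenced by landing alone in
    a bin.  The score is rounded to 10 decimals before ranking and ties
    break toward the lower gene index, making the ordering insensitive to
    float noise.  Returned indices are ordered by decreasing score.
    """
    X = np.asarray(X_raw, dtype=np.float64)
    n_genes = X.shape[1]
    if n_top > n_genes:
        raise ValueError(
            f"n_top={n_top} exceeds the {n_genes} genes available; pass "
            f"n_top={n_genes} to keep all genes (appropriate for targeted "
            "panels)"
        )
    Xe = np.expm1(normalize_expression(X))
    mu = Xe.mean(axis=0)
    var = Xe.var(axis=0, ddof=1) if Xe.shape[0] > 1 else np.zeros(n_genes)
    disp = np.divide(var, mu, out=np.zeros(n_genes), where=mu > 0)

    bins = pd.cut(mu, bins=20, labels=False, duplicates="drop")
    bins = np.asarray(bins, dtype=float)
    bins[np.isnan(bins)] = -1
    g_sd = disp.std(ddof=1) if n_genes > 1 else 0.0
    global_z = (disp - disp.mean()) / g_sd if g_sd > 0 else np.zeros(n_genes)
    disp_norm = np.zeros(n_genes)
    for b in np.unique(bins):
        mask = bins == b
        d = disp[mask]
        sd = d.std(ddof=1) if mask.sum() > 1 else 0.0
        disp_norm[mask] = (d - d.mean()) / sd if sd > 0 else global_z[mask]
    disp_norm = np.round(disp_norm, 10)
    # stable argsort on (-disp_norm) keeps the lower index on ties
    order = np.argsort(-disp_norm, kind="stable")
    return order[:n_top]


def extract_patches(image: np.ndarray, S: np.ndarray, size: int = 16,
                    spot_ids: list[str] | None = None) -> np.ndarray:
    """Cut one ``size × size × 3`` patch centered on each spot.

    Even sizes use the floor convention: for coordinate (x, y) the center
    pixel pair (floor(x), floor(x)+1) brackets x, likewise for y.  Patches
    that overlap the image border are completed by reflection padding.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be h × w × 3")
    if size <= 0 or size % 2 != 0:
        raise ValueError("patch size must be a positive even integer")
    S = np.asarray(S, dtype=np.float64)
    h, w = image.shape[:2]
    bad = np.flatnonzero((S[:, 0] < 0) | (S[:, 0] >= w) | (S[:, 1] < 0) | (S[:, 1] >= h))
    if bad.size:
        names = [spot_ids[i] if spot_ids else str(i) for i in bad]
        raise ValueError(f"coordinates outside the image for spots: {names}")
    pad = size
    padded = np.pad(image, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
    half = size // 2
    out = np.empty((S.shape[0], size, size, 3), dtype=image.dtype)
    cx = np.floor(S[:, 0]).astype(int)
    cy = np.floor(S[:, 1]).astype(int)
    for i in range(S.shape[0]):
        r0 = cy[i] - half + 1 + pad
        c0 = cx[i] - half + 1 + pad
        out[i] = padded[r0:r0 + size, c0:c0 + size]
    return out
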