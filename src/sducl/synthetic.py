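"""Synthetic spatial transcriptomics slides with known spatial domains.

The generator emulates the structure of annotated Visium-style slides: spots
on a regular grid partitioned into contiguous spatial domains (horizontal
bands mimicking cortical layers, or Voronoi patches mimicking tumor
mosaics); each domain owns a set of marker genes whose mean expression is
raised by ``exp(marker_log_fc)``; counts are negative-binomial with
per-spot lognormal sequencing depth; a small RGB slide image tints each
domain with its own base color plus Gaussian pixel noise, so image patches
carry domain signal.  Ground-truth domain ids are attached as labels.
Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SpatialDataset

__all__ = ["SyntheticSpec", "generate", "write_fixture_visium"]

_PALETTE = np.array(
    [
        [200, 80, 80],
        [80, 180, 90],
        [90, 90, 210],
        [210, 190, 70],
        [170, 80, 190],
        [70, 190, 190],
        [230, 140, 60],
        [120, 120, 120],
    ],
    dtype=float,
)

_SPACING_PX = 20  # pixel pitch between adjacent grid spots
_MARGIN_PX = 16


@dataclass
class SyntheticSpec:
    """Generation parameters; defaults give a layered three-domain slide.

    ``nb_dispersion`` is the negative-binomial overdispersion φ in
    Var = μ + φ·μ²; ``depth_mean`` the mean total counts per spot;
    ``marker_log_fc`` the natural-log fold change of a domain's markers.
    """

    grid_shape: tuple = (10, 30)
    n_domains: int = 3
    n_genes: int = 300
    n_markers_per_domain: int = 30
    marker_log_fc: float = 1.5
    nb_dispersion: float = 0.3
    depth_mean: float = 2000.0
    image_noise_sd: float = 10.0
    image_domain_contrast: float = 1.0
    layout: str = "layers"  # "layers" (contiguous bands) or "mosaic" (Voronoi)
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid_shape entries must be positive")
        if not 1 <= self.n_domains <= rows * cols:
            raise ValueError("n_domains must be in [1, n_spots]")
        if self.n_domains > len(_PALETTE):
            raise ValueError(f"at most {len(_PALETTE)} domains supported")
        if self.n_markers_per_domain * self.n_domains > self.n_genes:
            raise ValueError("more marker genes requested than genes")
        if self.nb_dispersion < 0 or self.depth_mean <= 0:
            raise ValueError("nb_dispersion must be >= 0 and depth_mean > 0")
        if self.layout not in ("layers", "mosaic"):
            raise ValueError(f"unknown layout {self.layout!r}")


def _domain_assignment(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    if spec.layout == "layers":
        # contiguous vertical bands along the column axis (layer-like)
        edges = np.linspace(0, cols, spec.n_domains + 1)
        dom = np.searchsorted(edges, cc.ravel(), side="right") - 1
        return np.clip(dom, 0, spec.n_domains - 1)
    centers = np.column_stack(
        [rng.uniform(0, rows, spec.n_domains), rng.uniform(0, cols, spec.n_domains)]
    )
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    return d2.argmin(axis=1)


def _nb_sample(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma–Poisson draw with Var = μ + φ μ² (φ = dispersion)."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate(spec: SyntheticSpec) -> SpatialDataset:
    """Draw one synthetic slide (counts, coords, image, labels) from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    n_spots = rows * cols

    domains = _domain_assignment(spec, rng)

    # per-gene baseline means: lognormal around an even split of the depth
    base = spec.depth_mean / spec.n_genes
    gene_mean = base * rng.lognormal(0.0, 0.5, size=spec.n_genes)
    # disjoint marker sets per domain
    marker_pool = rng.permutation(spec.n_genes)
    mean_matrix = np.tile(gene_mean, (spec.n_domains, 1))
    for d in range(spec.n_domains):
        genes = marker_pool[
            d * spec.n_markers_per_domain : (d + 1) * spec.n_markers_per_domain
        ]
        mean_matrix[d, genes] *= np.exp(spec.marker_log_fc)

    depth_factor = rng.lognormal(0.0, 0.25, size=n_spots)
    mu = mean_matrix[domains] * depth_factor[:, None]
    counts = _nb_sample(mu, spec.nb_dispersion, rng).astype(float)

    # grid coordinates in pixel units; jitter-free regular lattice
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pix = np.column_stack(
        [
            _MARGIN_PX + rr.ravel() * _SPACING_PX,
            _MARGIN_PX + cc.ravel() * _SPACING_PX,
        ]
    ).astype(float)

    # slide image: domain base color at each spot's footprint + noise;
    # image_domain_contrast blends palette vs neutral tissue (0 = no signal)
    H = 2 * _MARGIN_PX + (rows - 1) * _SPACING_PX
    W = 2 * _MARGIN_PX + (cols - 1) * _SPACING_PX
    neutral = np.array([235.0, 225.0, 225.0])
    img = np.full((H, W, 3), neutral)
    half = _SPACING_PX // 2
    t = float(np.clip(spec.image_domain_contrast, 0.0, 1.0))
    for i in range(n_spots):
        r, c = int(pix[i, 0]), int(pix[i, 1])
        color = t * _PALETTE[domains[i]] + (1.0 - t) * neutral
        img[max(r - half, 0) : r + half, max(c - half, 0) : c + half] = color
    img += rng.normal(0.0, spec.image_noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    return SpatialDataset(
        counts=counts,
        coords=pix.copy(),
        spot_ids=[f"SPOT-{i:05d}" for i in range(n_spots)],
        gene_ids=[f"gene_{g:04d}" for g in range(spec.n_genes)],
        image=img,
        pixel_coords=pix,
        spot_diameter_px=float(_SPACING_PX - 4),
        labels=pd.Categorical([f"domain_{d}" for d in domains]),
    )


def write_fixture_visium(
    ds: SpatialDataset, dir_path, dialect: str = "old"
) -> None:
    """Write ``ds`` as a minimal spaceranger-like directory.

    Produces a legacy MTX triplet (matrix.mtx, barcodes.tsv, genes.tsv), a
    tissue-positions CSV in the requested dialect ("old" headerless
    ``tissue_positions_list.csv`` or "new" headered
    ``tissue_positions.csv``), and — when the dataset has an image — a
    ``spatial/tissue_image.png`` plus scalefactors JSON.  The directory is
    readable by :func:`sducl.datasets.read_visium`.
    """
    import json

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    # 10x orientation: genes x cells
    X = ds.counts.T
    if np.allclose(X, np.rint(X)):
        mmwrite(dir_path / "matrix.mtx", csr_matrix(X.astype(np.int64)), field="integer")
    else:
        mmwrite(dir_path / "matrix.mtx", csr_matrix(X))
    pd.Series(ds.spot_ids).to_csv(
        dir_path / "barcodes.tsv", index=False, header=False
    )
    pd.DataFrame({"id": ds.gene_ids, "name": ds.gene_ids}).to_csv(
        dir_path / "genes.tsv", sep="\t", index=False, header=False
    )

    rows, cols = ds.coords[:, 0], ds.coords[:, 1]
    pos = pd.DataFrame(
        {
            "barcode": ds.spot_ids,
            "in_tissue": 1,
            "array_row": np.rint((rows - rows.min()) / _SPACING_PX).astype(int),
            "array_col": np.rint((cols - cols.min()) / _SPACING_PX).astype(int),
            "pxl_row_in_fullres": rows,
            "pxl_col_in_fullres": cols,
        }
    )
    if dialect == "old":
        pos.to_csv(dir_path / "tissue_positions_list.csv", index=False, header=False)
    elif dialect == "new":
        pos.to_csv(dir_path / "tissue_positions.csv", index=False)
    else:
        raise ValueError(f"unknown positions dialect {dialect!r}")

    if ds.image is not None:
        from PIL import Image

        spatial = dir_path / "spatial"
        spatial.mkdir(exist_ok=True)
        Image.fromarray(ds.image).save(spatial / "tissue_image.png")
        (spatial / "scalefactors_json.json").write_text(
            json.dumps({"spot_diameter_fullres": ds.spot_diameter_px})
        )
    if ds.labels is not None:
        pd.DataFrame({"barcode": ds.spot_ids, "label": list(ds.labels)}).to_csv(
            dir_path / "labels.csv", index=False
        )
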