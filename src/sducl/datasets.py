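"""In-memory data model and readers/writers for spatial transcriptomics inputs.

The central container is :class:`SpatialDataset`: a spot-by-gene count matrix,
per-spot 2-D coordinates, and optionally a full-slide histology raster with
per-spot pixel positions and ground-truth domain labels.  Readers cover the
10x Visium spaceranger layout (MTX triplet or feature-barcode ``.h5`` plus a
tissue-positions CSV), AnnData ``.h5ad`` containers, and plain CSV/TSV pairs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpatialDataset",
    "FormatError",
    "AlignmentError",
    "read_visium",
    "read_h5ad",
    "write_h5ad",
    "read_csv_pair",
    "crop_patches",
]


class FormatError(ValueError):
    """An input file or directory does not match the expected format."""


class AlignmentError(ValueError):
    """Row keys of two inputs that must align do not match."""


@dataclass
class SpatialDataset:
    """A spatial transcriptomics slide held in memory.

    Parameters
    ----------
    counts
        ``(n_spots, n_genes)`` nonnegative expression matrix (raw counts or
        normalized values), dense float array.
    coords
        ``(n_spots, 2)`` metric spatial positions used for neighbor graphs.
        For Visium these are full-resolution pixel coordinates, not array
        row/col indices.
    spot_ids, gene_ids
        Unique barcode / gene name vectors.
    image
        Optional ``(H, W, 3)`` uint8 histology raster.
    pixel_coords
        Optional ``(n_spots, 2)`` positions of spot centers in ``image``
        pixel units, ordered ``(row, col)``.
    spot_diameter_px
        Optional spot diameter in pixels (drives the default patch size).
    labels
        Optional per-spot ground-truth domain annotation.
    """

    counts: np.ndarray
    coords: np.ndarray
    spot_ids: Sequence[str]
    gene_ids: Sequence[str]
    image: Optional[np.ndarray] = None
    pixel_coords: Optional[np.ndarray] = None
    spot_diameter_px: Optional[float] = None
    labels: Optional[pd.Categorical] = None
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = list(map(str, self.spot_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        if self.labels is not None and not isinstance(self.labels, pd.Categorical):
            self.labels = pd.Categorical(self.labels)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[0] == 0:
            raise FormatError("counts must be a non-empty 2-D matrix")
        n = self.counts.shape[0]
        if np.min(self.counts) < 0:
            raise FormatError("counts contains negative entries")
        if self.coords.shape != (n, 2):
            raise AlignmentError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.spot_ids) != n:
            raise AlignmentError("spot_ids length does not match counts rows")
        if len(set(self.spot_ids)) != n:
            raise FormatError("spot barcodes are not unique")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise AlignmentError("gene_ids length does not match counts columns")
        if self.labels is not None and len(self.labels) != n:
            raise AlignmentError("labels length does not match counts rows")
        if self.image is not None:
            if self.pixel_coords is None or self.spot_diameter_px is None:
                raise FormatError(
                    "image present but pixel_coords/spot_diameter_px missing"
                )
            if self.pixel_coords.shape != (n, 2):
                raise AlignmentError("pixel_coords shape does not match spots")
            if self.spot_diameter_px <= 0:
                raise FormatError("spot_diameter_px must be positive")
        self._validated = True

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    # -- conversion -----------------------------------------------------
    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (spatial slot in ``obsm``)."""
        import anndata as ad

        adata = ad.AnnData(
            X=np.asarray(self.counts, dtype=np.float32),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids, name="barcode")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene")),
        )
        adata.obsm["spatial"] = np.asarray(self.coords, dtype=float)
        if self.pixel_coords is not None:
            adata.obsm["pixel"] = np.asarray(self.pixel_coords, dtype=float)
        if self.labels is not None:
            adata.obs["label"] = pd.Categorical(
                self.labels, categories=self.labels.categories
            )
        if self.image is not None:
            adata.uns["image"] = np.asarray(self.image)
        if self.spot_diameter_px is not None:
            adata.uns["spot_diameter_px"] = float(self.spot_diameter_px)
        # integer counts survive the float32 cast exactly below 2**24
        adata.layers["counts"] = np.asarray(self.counts, dtype=np.float64)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "SpatialDataset":
        if "spatial" not in adata.obsm:
            raise FormatError("AnnData has no obsm['spatial'] coordinate slot")
        counts = adata.layers.get("counts", adata.X)
        if hasattr(counts, "toarray"):
            counts = counts.toarray()
        labels = None
        if "label" in adata.obs:
            labels = pd.Categorical(adata.obs["label"])
        return cls(
            counts=np.asarray(counts, dtype=float),
            coords=np.asarray(adata.obsm["spatial"], dtype=float),
            spot_ids=list(adata.obs_names),
            gene_ids=list(adata.var_names),
            image=adata.uns.get("image"),
            pixel_coords=np.asarray(adata.obsm["pixel"], dtype=float)
            if "pixel" in adata.obsm
            else None,
            spot_diameter_px=adata.uns.get("spot_diameter_px"),
            labels=labels,
        )


# ---------------------------------------------------------------------------
# Visium reader
# ---------------------------------------------------------------------------

_POSITION_COLS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _read_positions(path: Path) -> pd.DataFrame:
    """Parse a Visium tissue-positions CSV, auto-detecting dialect.

    Old spaceranger writes a headerless six-column
    ``tissue_positions_list.csv``; newer versions write ``tissue_positions.csv``
    with a header line.  Both carry the same columns.
    """
    with open(path) as fh:
        first = fh.readline()
    header = 0 if "barcode" in first.lower() else None
    df = pd.read_csv(path, header=header)
    if df.shape[1] < 6:
        raise FormatError(f"positions file {path.name} has {df.shape[1]} columns, expected 6")
    df = df.iloc[:, :6]
    df.columns = _POSITION_COLS
    df["barcode"] = df["barcode"].astype(str)
    return df.set_index("barcode")


def _find_positions_file(dir_path: Path) -> Path:
    for sub in ("", "spatial"):
        for name in ("tissue_positions_list.csv", "tissue_positions.csv"):
            cand = dir_path / sub / name
            if cand.is_file():
                return cand
    raise FormatError(
        f"no tissue positions CSV (tissue_positions[_list].csv) found under {dir_path}"
    )


def read_visium(dir_path: os.PathLike | str) -> SpatialDataset:
    """Read a spaceranger-style Visium directory into a :class:`SpatialDataset`.

    The directory must contain either an MTX triplet (``matrix.mtx[.gz]`` +
    barcodes + features/genes, optionally under ``filtered_feature_bc_matrix/``)
    or a 10x feature-barcode ``.h5``, plus a tissue-positions CSV.  Spots
    flagged ``in_tissue == 0`` are dropped; coordinates are taken from the
    full-resolution pixel columns.  A ``spatial/tissue_image.png`` (or
    ``image.png``) raster is attached when present.
    """
    import scanpy as sc

    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise FormatError(f"{dir_path} is not a directory")

    mtx_dir = None
    for sub in ("", "filtered_feature_bc_matrix"):
        d = dir_path / sub
        if any((d / f"matrix.mtx{ext}").is_file() for ext in ("", ".gz")):
            mtx_dir = d
            break
    h5_files = sorted(dir_path.glob("*feature_bc_matrix.h5")) or sorted(
        dir_path.glob("*.h5")
    )
    if mtx_dir is not None:
        adata = sc.read_10x_mtx(mtx_dir)
    elif h5_files:
        adata = sc.read_10x_h5(h5_files[0])
    else:
        raise FormatError(
            f"no matrix found under {dir_path}: expected matrix.mtx[.gz] triplet "
            "or a feature-barcode .h5"
        )
    adata.var_names_make_unique()

    pos = _read_positions(_find_positions_file(dir_path))
    barcodes = [str(b) for b in adata.obs_names]
    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} matrix barcodes absent from the positions file"
        )
    pos = pos.loc[barcodes]
    keep = pos["in_tissue"].astype(int).to_numpy() == 1

    X = adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    X = np.asarray(X, dtype=float)[keep]
    pos = pos.loc[keep]
    pix = pos[["pxl_row_in_fullres", "pxl_col_in_fullres"]].to_numpy(dtype=float)

    image = None
    spot_diameter = None
    for sub in ("spatial", ""):
        for name in ("tissue_image.png", "image.png", "tissue_hires_image.png"):
            cand = dir_path / sub / name
            if cand.is_file():
                from PIL import Image

                image = np.asarray(Image.open(cand).convert("RGB"))
                break
        if image is not None:
            break
    if image is not None:
        import json

        sf = dir_path / "spatial" / "scalefactors_json.json"
        if sf.is_file():
            spot_diameter = float(
                json.loads(sf.read_text()).get("spot_diameter_fullres", 32.0)
            )
        else:
            spot_diameter = 32.0

    return SpatialDataset(
        counts=X,
        coords=pix.copy(),
        spot_ids=list(pos.index),
        gene_ids=list(adata.var_names),
        image=image,
        pixel_coords=pix if image is not None else None,
        spot_diameter_px=spot_diameter,
    )


# ---------------------------------------------------------------------------
# h5ad / CSV readers
# ---------------------------------------------------------------------------


def read_h5ad(path: os.PathLike | str) -> SpatialDataset:
    """Read an AnnData ``.h5ad`` file carrying an ``obsm['spatial']`` slot."""
    import anndata as ad

    return SpatialDataset.from_anndata(ad.read_h5ad(path))


def write_h5ad(ds: SpatialDataset, path: os.PathLike | str) -> None:
    """Write a :class:`SpatialDataset` to ``.h5ad`` (round-trips exactly)."""
    ds.to_anndata().write_h5ad(Path(path))


def read_csv_pair(
    counts_path: os.PathLike | str,
    coords_path: os.PathLike | str,
    labels_path: os.PathLike | str | None = None,
) -> SpatialDataset:
    """Read a counts table and a 2-column coordinate table sharing row keys.

    Separator is sniffed from the extension (``.tsv``/``.txt`` → tab).  The
    coordinate table is aligned to the counts rows by index; disjoint keys
    raise :class:`AlignmentError`.
    """

    def _read(p):
        p = Path(p)
        sep = "\t" if p.suffix in {".tsv", ".txt"} else ","
        return pd.read_csv(p, sep=sep, index_col=0)

    counts = _read(counts_path)
    coords = _read(coords_path)
    common = counts.index.intersection(coords.index)
    if len(common) == 0:
        raise AlignmentError("counts and coords tables share no row keys")
    if len(common) < len(counts):
        raise AlignmentError(
            f"{len(counts) - len(common)} spots in counts have no coordinates"
        )
    coords = coords.loc[counts.index]
    labels = None
    if labels_path is not None:
        lab = _read(labels_path)
        labels = pd.Categorical(lab.loc[counts.index].iloc[:, 0])
    return SpatialDataset(
        counts=counts.to_numpy(dtype=float),
        coords=coords.iloc[:, :2].to_numpy(dtype=float),
        spot_ids=list(counts.index.astype(str)),
        gene_ids=list(counts.columns.astype(str)),
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Patch cropping
# ---------------------------------------------------------------------------


def crop_patches(ds: SpatialDataset, patch_px: Optional[int] = None) -> np.ndarray:
    """Crop one square patch per spot from the slide image.

    Each patch is ``patch_px × patch_px × 3``, centered on the spot's pixel
    coordinate; windows whose center is nearer than ``patch_px/2`` to an edge
    are shifted inward so the output size is constant.  ``patch_px`` defaults
    to ``round(spot_diameter_px)``.
    """
    if ds.image is None:
        raise ValueError("dataset has no image; cannot crop patches")
    if patch_px is None:
        patch_px = int(round(ds.spot_diameter_px)) if ds.spot_diameter_px else 32
    patch_px = int(patch_px)
    H, W = ds.image.shape[:2]
    if patch_px > H or patch_px > W:
        raise ValueError(f"patch_px={patch_px} exceeds image dimensions {H}x{W}")
    half = patch_px // 2
    out = np.empty((ds.n_spots, patch_px, patch_px, 3), dtype=ds.image.dtype)
    for i, (r, c) in enumerate(np.asarray(ds.pixel_coords)):
        r0 = int(np.clip(int(round(r)) - half, 0, H - patch_px))
        c0 = int(np.clip(int(round(c)) - half, 0, W - patch_px))
        out[i] = ds.image[r0 : r0 + patch_px, c0 : c0 + patch_px, :3]
    return out
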