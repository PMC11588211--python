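"""Feature augmentation: gene expression, image, and Katz topology blocks.

The model input is a fused matrix F = Eg ⊕ Ei ⊕ Es — column-wise
concatenation ("splicing") of a gene-expression block, an optional histology
image-feature block, and an optional spatial-topology block derived from the
Katz index of the spot graph.  Each block is z-standardized per column before
fusion so no modality dominates by scale; dropping Ei or Es reproduces the
"without image" / "without Katz" ablations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np

from .graph import SpatialGraph

__all__ = [
    "AugmentedFeatures",
    "KatzMatrix",
    "preprocess_genes",
    "extract_image_features",
    "katz_features",
    "fuse",
    "standardize_columns",
]


@dataclass
class KatzMatrix:
    """Pairwise Katz indices of the spot graph.

    ``K[i, j] = Σ_{l≥1} β^l (A^l)[i, j]`` counts all paths between i and j,
    geometrically attenuated in length by ``beta``; the closed form is
    ``(I − βA)^{-1} − I``, finite iff ``β < 1/ρ(A)``.
    """

    K: np.ndarray
    beta: float
    l_max: object  # int truncation length or "closed-form"


@dataclass
class AugmentedFeatures:
    """The fused model input F with its per-block column ranges."""

    F: np.ndarray
    Eg: np.ndarray
    Ei: Optional[np.ndarray] = None
    Es: Optional[np.ndarray] = None
    block_slices: Dict[str, slice] = None

    @property
    def n_spots(self) -> int:
        return self.F.shape[0]

    @property
    def dim(self) -> int:
        return self.F.shape[1]


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance columns; constant columns map to zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


# ---------------------------------------------------------------------------
# Gene expression block
# ---------------------------------------------------------------------------


def preprocess_genes(ds, n_hvg: int = 3000) -> np.ndarray:
    """Standard expression preprocessing into the Eg block.

    Library-size normalize each spot to the median total count, log1p,
    keep the ``n_hvg`` highest-variance genes (ties broken by gene order),
    and z-score the columns.  All-zero spots are left as zero vectors with
    a warning.
    """
    X = np.asarray(ds.counts, dtype=float)
    depth = X.sum(axis=1)
    if np.any(depth == 0):
        warnings.warn(f"{int((depth == 0).sum())} spot(s) have zero total counts")
    target = np.median(depth[depth > 0]) if np.any(depth > 0) else 1.0
    scale = np.where(depth > 0, target / np.where(depth > 0, depth, 1.0), 0.0)
    Xn = np.log1p(X * scale[:, None])
    if n_hvg < Xn.shape[1]:
        var = Xn.var(axis=0)
        # stable sort on -var keeps gene order among exact ties
        top = np.argsort(-var, kind="stable")[:n_hvg]
        top.sort()
        Xn = Xn[:, top]
    return standardize_columns(Xn)


# ---------------------------------------------------------------------------
# Image feature block
# ---------------------------------------------------------------------------


def _patchstats_features(patches: np.ndarray) -> np.ndarray:
    """Deterministic per-channel summary features: mean, variance, 8-bin
    histogram for each RGB channel (30 features per patch)."""
    patches = np.asarray(patches, dtype=float)
    n = patches.shape[0]
    feats = np.empty((n, 30), dtype=float)
    edges = np.linspace(0.0, 255.0, 9)
    for i in range(n):
        cols = []
        for c in range(3):
            ch = patches[i, :, :, c].ravel()
            hist = np.histogram(ch, bins=edges)[0] / ch.size
            cols.extend([ch.mean(), ch.var(), *hist])
        feats[i] = cols
    return feats


def _resnet50_features(patches: np.ndarray) -> np.ndarray:  # pragma: no cover
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "the 'resnet50' backbone needs torch+torchvision with pretrained "
            "weights; use backbone='patchstats' for a dependency-free extractor"
        ) from exc
    raise NotImplementedError("pretrained CNN backbone not bundled")


_BACKBONES: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "patchstats": _patchstats_features,
    "resnet50": _resnet50_features,
}


def register_backbone(name: str, fn: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a custom patch-stack → feature-matrix extractor."""
    _BACKBONES[name] = fn


def extract_image_features(
    patches: np.ndarray, backbone: str = "patchstats", d_i: int = 50, seed: int = 0
) -> np.ndarray:
    """Per-spot morphology features from the patch stack.

    ``patchstats`` (default) computes deterministic channel statistics
    (30-d); a pretrained-CNN backbone can be plugged in via
    :func:`register_backbone`.  Features wider than ``d_i`` are compressed
    with truncated SVD; the output is column-standardized.
    """
    if backbone not in _BACKBONES:
        raise ValueError(
            f"unknown backbone {backbone!r}; available: {sorted(_BACKBONES)}"
        )
    feats = _BACKBONES[backbone](np.asarray(patches))
    if feats.shape[1] > d_i:
        from sklearn.decomposition import TruncatedSVD

        feats = TruncatedSVD(n_components=d_i, random_state=seed).fit_transform(
            feats - feats.mean(axis=0)
        )
    return standardize_columns(feats)


# ---------------------------------------------------------------------------
# Katz spatial-topology block
# ---------------------------------------------------------------------------


def katz_matrix(
    A: np.ndarray, beta: float = 0.1, l_max: object = "closed-form"
) -> KatzMatrix:
    """Compute the Katz index matrix of adjacency ``A``.

    ``l_max="closed-form"`` evaluates ``(I − βA)^{-1} − I``; an integer
    truncates the path sum at length ``l_max``.  If ``β ≥ 1/ρ(A)`` the series
    diverges, so β is shrunk to ``0.9/ρ(A)`` with a warning.
    """
    A = np.asarray(A, dtype=float)
    if beta <= 0:
        raise ValueError("beta must be positive")
    n = A.shape[0]
    if np.any(A):
        rho = float(np.max(np.abs(np.linalg.eigvalsh(A))))
    else:
        rho = 0.0
    if rho > 0 and beta >= 1.0 / rho:
        new_beta = 0.9 / rho
        warnings.warn(
            f"beta={beta} >= 1/spectral_radius={1.0 / rho:.4g}; shrinking to "
            f"{new_beta:.4g} so the path series converges"
        )
        beta = new_beta
    if l_max == "closed-form":
        K = np.linalg.inv(np.eye(n) - beta * A) - np.eye(n)
    else:
        l_max = int(l_max)
        if l_max < 1:
            raise ValueError("l_max must be >= 1")
        K = np.zeros_like(A)
        P = np.eye(n)
        for _ in range(l_max):
            P = beta * (P @ A)
            K += P
    return KatzMatrix(K=K, beta=beta, l_max=l_max)


def katz_features(
    graph: SpatialGraph,
    beta: float = 0.1,
    l_max: object = "closed-form",
    d_s: int = 32,
) -> tuple[KatzMatrix, np.ndarray]:
    """Per-node spatial-topology features Es from the Katz matrix.

    The N×N Katz matrix is compressed to ``d_s`` columns by SVD: row i of
    ``Es`` is node i's loading on the dominant singular directions, scaled by
    the singular values, then column-standardized.  Singular-vector signs are
    fixed (largest-magnitude component positive) for reproducibility.
    """
    km = katz_matrix(graph.A, beta=beta, l_max=l_max)
    n = km.K.shape[0]
    d_s = min(d_s, n)
    # K is symmetric: use the eigendecomposition as an exact SVD
    w, V = np.linalg.eigh(km.K)
    order = np.argsort(-np.abs(w), kind="stable")[:d_s]
    sv = np.abs(w[order])
    U = V[:, order]
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(d_s)])
    flip[flip == 0] = 1.0
    Es = U * flip * sv
    return km, standardize_columns(Es)


# ---------------------------------------------------------------------------
# Tensor fusion
# ---------------------------------------------------------------------------


def fuse(
    Eg: np.ndarray,
    Ei: Optional[np.ndarray] = None,
    Es: Optional[np.ndarray] = None,
) -> AugmentedFeatures:
    """Splice the present feature blocks into F = Eg ⊕ Ei ⊕ Es.

    Blocks are column-standardized before concatenation; missing blocks are
    skipped (the without-image / without-Katz ablations).  ``block_slices``
    records where each block landed in F.
    """
    blocks = [("Eg", Eg)]
    if Ei is not None:
        blocks.append(("Ei", Ei))
    if Es is not None:
        blocks.append(("Es", Es))
    n = blocks[0][1].shape[0]
    for name, B in blocks:
        if B.shape[0] != n:
            raise ValueError(
                f"block {name} has {B.shape[0]} rows, expected {n}"
            )
    std = {name: standardize_columns(B) for name, B in blocks}
    F = np.concatenate([std[name] for name, _ in blocks], axis=1)
    slices, start = {}, 0
    for name, _ in blocks:
        width = std[name].shape[1]
        slices[name] = slice(start, start + width)
        start += width
    return AugmentedFeatures(
        F=F,
        Eg=std["Eg"],
        Ei=std.get("Ei"),
        Es=std.get("Es"),
        block_slices=slices,
    )
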