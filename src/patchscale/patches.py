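"""Patch extraction, overlap-averaged reassembly, and coupled dictionaries.

The downscaling scheme works on small square blocks of contiguous pixels
("patches").  A coupled dictionary pairs each vectorized low-resolution
training patch (an *atom* of ``D_l``, edge ``p``, dimension ``q = p**2``)
with the vectorized high-frequency residual patch covering the same ground
footprint at the fine scale (a column of ``D_h``, edge ``s*p``, dimension
``s**2 * q``).  Whatever sparse combination of LR atoms explains a query
patch, the same coefficients applied to the HR columns synthesize its
residual — the geometric-similarity assumption at the heart of the method.

Stored ``D_l`` columns have unit Euclidean norm and the paired ``D_h``
columns are divided by the same LR norm, so the coupled linear model is
preserved under query-patch normalization; ``atom_norms`` recovers the raw
training patches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, Union

import numpy as np

from .raster import RasterBand, residual_field

PATCH_EDGE_DEFAULT = 3


def _origins(dim: int, patch_edge: int, stride: int) -> List[int]:
    """Patch origins along one axis: multiples of *stride*, plus one
    right-aligned extra so every cell is covered."""
    last = dim - patch_edge
    origins = list(range(0, last + 1, stride))
    if origins[-1] != last:
        origins.append(last)
    return origins


@dataclass
class PatchSet:
    """Vectorized patches plus the geometry needed to re-assemble them.

    ``vectors`` holds one column per patch (length ``patch_edge**2``,
    row-major within the patch); ``origin_grid`` lists the (row, col) origin
    of each column in source-image coordinates.
    """

    vectors: np.ndarray
    patch_edge: int
    stride: int
    origin_grid: List[Tuple[int, int]]
    source_shape: Tuple[int, int]

    def __post_init__(self) -> None:
        q = self.patch_edge ** 2
        if self.vectors.ndim != 2 or self.vectors.shape[0] != q:
            raise ValueError(f"vectors must be {q} x N, got {self.vectors.shape}")
        if self.vectors.shape[1] != len(self.origin_grid):
            raise ValueError("one origin per patch column required")
        for (r, c) in self.origin_grid:
            if r + self.patch_edge > self.source_shape[0] or c + self.patch_edge > self.source_shape[1]:
                raise ValueError(f"origin ({r},{c}) overruns source shape {self.source_shape}")

    @property
    def n_patches(self) -> int:
        return self.vectors.shape[1]


def extract_patches(
    band: RasterBand, patch_edge: int, stride: int = 1, drop_masked: bool = True
) -> PatchSet:
    """Slice a band into vectorized, possibly overlapping patches.

    Origins run row-major over multiples of *stride* with right/bottom
    aligned extras so the patches cover every cell.  With ``drop_masked``
    set, any patch touching a masked cell is omitted (the surviving origins
    are recorded).
    """
    m, n = band.shape
    if patch_edge < 1 or stride < 1:
        raise ValueError("patch_edge and stride must be >= 1")
    if patch_edge > m or patch_edge > n:
        raise ValueError(f"patch_edge {patch_edge} exceeds image shape {band.shape}")
    rows = _origins(m, patch_edge, stride)
    cols = _origins(n, patch_edge, stride)
    vecs, origins = [], []
    for r in rows:
        for c in cols:
            if drop_masked and band.mask[r : r + patch_edge, c : c + patch_edge].any():
                continue
            vecs.append(band.values[r : r + patch_edge, c : c + patch_edge].ravel())
            origins.append((r, c))
    vectors = (
        np.stack(vecs, axis=1) if vecs else np.empty((patch_edge ** 2, 0))
    )
    return PatchSet(vectors, patch_edge, stride, origins, (m, n))


def assemble_patches(patches: PatchSet, target_shape: Tuple[int, int]) -> RasterBand:
    """Overlap-aware inverse of extraction.

    Each output cell is the unweighted mean of every patch value covering
    it; cells covered by no patch are masked.  Averaging over overlaps is
    the standard remedy against blocking artifacts.
    """
    if patches.source_shape != tuple(target_shape):
        raise ValueError(
            f"patch geometry built for {patches.source_shape}, target is {tuple(target_shape)}"
        )
    p = patches.patch_edge
    acc = np.zeros(target_shape)
    cnt = np.zeros(target_shape)
    for k, (r, c) in enumerate(patches.origin_grid):
        acc[r : r + p, c : c + p] += patches.vectors[:, k].reshape(p, p)
        cnt[r : r + p, c : c + p] += 1.0
    mask = cnt == 0
    vals = np.divide(acc, cnt, out=np.zeros_like(acc), where=~mask)
    return RasterBand(vals, mask)


@dataclass
class CoupledDictionary:
    """Paired low-resolution / high-resolution-residual example dictionaries.

    These are raw training patches, not learned atoms: ``D_l`` is
    ``q x M`` with unit-norm columns, ``D_h`` is ``s**2*q x M`` with each
    column divided by the matching LR norm, and ``atom_norms`` (length M)
    undoes the normalization.
    """

    D_l: np.ndarray
    D_h: np.ndarray
    s: int
    patch_edge: int
    band: str
    atom_norms: np.ndarray
    lr_kernel: str = "bicubic"
    residual_mode: bool = True  # D_h holds residual patches (vs raw HR patches)

    def __post_init__(self) -> None:
        q = self.patch_edge ** 2
        M = self.D_l.shape[1]
        if self.D_l.shape != (q, M):
            raise ValueError(f"D_l must be {q} x M, got {self.D_l.shape}")
        if self.D_h.shape != (self.s ** 2 * q, M):
            raise ValueError(f"D_h must be {self.s**2 * q} x {M}, got {self.D_h.shape}")
        if M < 1:
            raise ValueError("dictionary must hold at least one atom")
        norms = np.linalg.norm(self.D_l, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("D_l columns must have unit Euclidean norm")

    @property
    def n_atoms(self) -> int:
        return self.D_l.shape[1]

    # -- persistence (single .npz archive holding matrices + metadata) -----

    def save(self, path) -> None:
        meta = json.dumps(
            {
                "s": int(self.s),
                "patch_edge": int(self.patch_edge),
                "band": self.band,
                "lr_kernel": self.lr_kernel,
                "residual_mode": bool(self.residual_mode),
            }
        )
        np.savez(path, D_l=self.D_l, D_h=self.D_h, atom_norms=self.atom_norms,
                 meta=np.array(meta))

    @classmethod
    def load(cls, path) -> "CoupledDictionary":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(z["D_l"], z["D_h"], meta["s"], meta["patch_edge"],
                       meta["band"], z["atom_norms"], meta["lr_kernel"],
                       meta["residual_mode"])


def build_coupled_dictionary(
    pairs: Sequence[Tuple[RasterBand, RasterBand]],
    s: int,
    patch_edge: int = PATCH_EDGE_DEFAULT,
    stride: int = 1,
    kernel: str = "bicubic",
    residual_mode: bool = True,
) -> CoupledDictionary:
    """Collect coupled training patches from coincident (lr, hr) image pairs.

    For each pair the residual field ``X_r = hr - I_s(lr)`` is formed; LR
    patches (edge ``patch_edge``, the given stride) come from the native
    coarse grid and the paired residual patch (edge ``s*patch_edge``) from
    origin ``s*(r, c)`` of the residual — the same ground footprint.  Patch
    pairs touching masked cells and LR patches of zero norm are dropped.
    With ``residual_mode`` off, ``D_h`` stores raw HR patches instead.
    """
    if not pairs:
        raise ValueError("at least one (lr, hr) pair required")
    bands = {lr.band for lr, _ in pairs} | {hr.band for _, hr in pairs}
    if len(bands) != 1:
        raise ValueError(f"mixed bands in training pairs: {sorted(bands)}")
    band = bands.pop()

    p = patch_edge
    cols_l, cols_h = [], []
    for lr, hr in pairs:
        if hr.shape != (s * lr.shape[0], s * lr.shape[1]):
            raise ValueError(
                f"pair not co-registered at s={s}: lr {lr.shape}, hr {hr.shape}"
            )
        hi = residual_field(hr, lr, s, kernel) if residual_mode else hr
        for r in _origins(lr.shape[0], p, stride):
            for c in _origins(lr.shape[1], p, stride):
                if lr.mask[r : r + p, c : c + p].any():
                    continue
                hr_win_mask = hi.mask[s * r : s * (r + p), s * c : s * (c + p)]
                if hr_win_mask.any():
                    continue
                yl = lr.values[r : r + p, c : c + p].ravel()
                yh = hi.values[s * r : s * (r + p), s * c : s * (c + p)].ravel()
                cols_l.append(yl)
                cols_h.append(yh)

    if not cols_l:
        raise ValueError(
            "no valid patch pairs survived masking; reduce patch_edge or stride, "
            "or check the nodata masks"
        )
    D_l = np.stack(cols_l, axis=1)
    D_h = np.stack(cols_h, axis=1)
    norms = np.linalg.norm(D_l, axis=0)
    keep = norms > 0
    if not keep.any():
        raise ValueError("all candidate LR patches have zero norm")
    D_l, D_h, norms = D_l[:, keep], D_h[:, keep], norms[keep]
    return CoupledDictionary(
        D_l / norms, D_h / norms, s, p, band, norms, kernel, residual_mode
    )
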