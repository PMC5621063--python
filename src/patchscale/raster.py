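"""Raster data model and scale-change operators.

A :class:`RasterBand` is a 2-D grid of physical values (surface reflectance in
[0, 1] or brightness temperature in kelvin) with an explicit nodata mask and a
ground sample distance.  The three operators defined here — block aggregation,
interpolation upscaling, and the residual field — are the building blocks of
the downscaling scheme: a coarse sensor is modelled as an aggregation of the
fine field, the smooth part of the fine field is recovered by interpolation,
and the difference (the residual field ``X_r = X_h - I_s(X_l)``) is the
high-frequency content the sparse-coding stage reconstructs.

Conventions: 0-based row-major indexing; the low-resolution cell ``(i, j)``
corresponds to the high-resolution block ``[s*i, s*i+s) x [s*j, s*j+s)``.
Mask semantics: ``mask[i, j] is True`` means the cell holds no data.  Nodata
propagation is pessimistic — any output cell whose computation touches a
masked input cell is masked — except for ``block_aggregate``'s explicit
valid-fraction rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

BAND_LABELS = ("red", "green", "blue", "nir", "thermal")

#: interpolation kernels accepted by :func:`interpolate_upscale`, mapped to
#: spline orders for ``scipy.ndimage.map_coordinates`` and the half-width of
#: their footprint in input cells (used for pessimistic mask propagation).
KERNELS = {"nearest": (0, 0), "bilinear": (1, 1), "bicubic": (3, 2)}

REFLECTANCE_TOL = 1e-6


@dataclass
class RasterBand:
    """One co-registered spectral band on a regular grid.

    Parameters
    ----------
    values : ndarray of float, shape (rows, cols)
        Physical values; content of masked cells is irrelevant.
    mask : ndarray of bool, same shape
        True where the cell holds no data.
    pixel_size : float
        Ground sample distance in meters.
    band : str
        One of ``red, green, blue, nir, thermal``.
    """

    values: np.ndarray
    mask: np.ndarray = None
    pixel_size: float = 1.0
    band: str = "red"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError(f"values must be a non-empty 2-D grid, got shape {self.values.shape}")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if self.band not in BAND_LABELS:
            raise ValueError(f"unknown band {self.band!r}; expected one of {BAND_LABELS}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def is_reflectance(self) -> bool:
        """Reflectance bands are unitless in [0, 1]; thermal is in kelvin."""
        return self.band != "thermal"

    def valid_values(self) -> np.ndarray:
        """Flat array of values on unmasked cells."""
        return self.values[~self.mask]

    def copy(self) -> "RasterBand":
        return RasterBand(self.values.copy(), self.mask.copy(), self.pixel_size, self.band)

    def validate_range(self, tol: float = REFLECTANCE_TOL) -> None:
        """Raise if a reflectance band strays outside [0, 1] beyond *tol*."""
        if self.is_reflectance and self.valid_values().size:
            vmin, vmax = self.valid_values().min(), self.valid_values().max()
            if vmin < -tol or vmax > 1 + tol:
                raise ValueError(
                    f"reflectance band {self.band!r} outside [0,1]: range [{vmin}, {vmax}]"
                )


@dataclass
class Scene:
    """A set of co-registered bands sharing one grid.

    All member bands must agree in shape and pixel size; this is the container
    for one acquisition of one platform (coarse satellite or fine aircraft).
    """

    bands: Dict[str, RasterBand]
    acquired: str = ""
    platform: str = ""

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("Scene needs at least one band")
        shapes = {b.shape for b in self.bands.values()}
        sizes = {b.pixel_size for b in self.bands.values()}
        if len(shapes) != 1 or len(sizes) != 1:
            raise ValueError(f"bands disagree on grid: shapes {shapes}, pixel sizes {sizes}")
        for label, b in self.bands.items():
            if label != b.band:
                raise ValueError(f"band stored under {label!r} labels itself {b.band!r}")

    @property
    def shape(self) -> tuple:
        return next(iter(self.bands.values())).shape

    @property
    def pixel_size(self) -> float:
        return next(iter(self.bands.values())).pixel_size

    def map_bands(self, fn) -> "Scene":
        return Scene({k: fn(v) for k, v in self.bands.items()}, self.acquired, self.platform)


# ---------------------------------------------------------------------------
# scale-change operators
# ---------------------------------------------------------------------------


def block_aggregate(
    band: RasterBand, factor: int, min_valid_fraction: float = 1.0
) -> RasterBand:
    """Aggregate to a coarser grid by averaging ``factor x factor`` blocks.

    Each output cell is the mean of the *valid* cells of its block; the cell
    is masked when the valid fraction falls below ``min_valid_fraction``.
    Dimensions not divisible by ``factor`` are cropped at the trailing edge
    (with a warning).  This is the ideal-box aggregation used both to emulate
    the coarse sensor and to bring fine imagery onto a coarse grid.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 2:
        raise ValueError(f"factor must be an integer >= 2, got {factor!r}")
    if not (0 < min_valid_fraction <= 1):
        raise ValueError("min_valid_fraction must lie in (0, 1]")
    r, c = band.shape
    rr, cc = (r // factor) * factor, (c // factor) * factor
    if rr == 0 or cc == 0:
        raise ValueError(f"band shape {band.shape} smaller than factor {factor}")
    if (rr, cc) != (r, c):
        warnings.warn(
            f"block_aggregate: cropping {band.shape} to ({rr}, {cc}) "
            f"(dimensions not divisible by {factor})",
            stacklevel=2,
        )
    vals = band.values[:rr, :cc]
    valid = ~band.mask[:rr, :cc]
    blocks_v = vals.reshape(rr // factor, factor, cc // factor, factor)
    blocks_m = valid.reshape(rr // factor, factor, cc // factor, factor)
    n_valid = blocks_m.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        out = np.where(blocks_m, blocks_v, 0.0).sum(axis=(1, 3)) / np.maximum(n_valid, 1)
    out_mask = n_valid < min_valid_fraction * factor * factor - 1e-12
    out = np.where(out_mask, 0.0, out)
    return RasterBand(out, out_mask, band.pixel_size * factor, band.band)


def interpolate_upscale(band: RasterBand, s: int, kernel: str = "bicubic") -> RasterBand:
    """Upsample by an integer factor *s* — the interpolation operator ``I_s``.

    Output cell centers are placed at input coordinates ``(I + 0.5)/s - 0.5``
    so that grids remain center-aligned: with the nearest kernel each input
    cell is exactly replicated into its ``s x s`` block, and aggregating back
    at the same factor is the identity.  Any output cell whose kernel
    footprint touches a masked input cell is masked.
    """
    if not isinstance(s, (int, np.integer)) or s < 2:
        raise ValueError(f"scale factor must be an integer >= 2, got {s!r}")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; valid kernels: {sorted(KERNELS)}")
    order, halfwidth = KERNELS[kernel]
    m, n = band.shape
    rows = (np.arange(s * m) + 0.5) / s - 0.5
    cols = (np.arange(s * n) + 0.5) / s - 0.5
    ri, ci = np.meshgrid(rows, cols, indexing="ij")

    vals = band.values
    if band.mask.any():
        # fill masked cells with the valid mean so spline weights stay finite;
        # every contaminated output cell is masked below anyway
        fill = band.valid_values().mean() if (~band.mask).any() else 0.0
        vals = np.where(band.mask, fill, vals)
    if kernel == "nearest":
        out = np.repeat(np.repeat(vals, s, axis=0), s, axis=1)
    else:
        out = ndimage.map_coordinates(vals, [ri, ci], order=order, mode="nearest")

    if band.mask.any():
        dil = ndimage.binary_dilation(band.mask, structure=np.ones((2 * halfwidth + 1,) * 2))
        out_mask = np.repeat(np.repeat(dil, s, axis=0), s, axis=1)
    else:
        out_mask = np.zeros_like(out, dtype=bool)
    return RasterBand(out, out_mask, band.pixel_size / s, band.band)


def residual_field(
    hr: RasterBand, lr: RasterBand, s: int, kernel: str = "bicubic"
) -> RasterBand:
    """High-frequency residual ``X_r = X_h - I_s(X_l)``.

    This is the field lost by the coarse sensor and reconstructed patch-wise
    from the coupled dictionaries; adding it back to the interpolated coarse
    image recovers the fine image exactly on valid cells.
    """
    if hr.band != lr.band:
        raise ValueError(f"band mismatch: hr={hr.band!r}, lr={lr.band!r}")
    expect = (s * lr.shape[0], s * lr.shape[1])
    if hr.shape != expect:
        raise ValueError(
            f"shape mismatch: hr {hr.shape} != s * lr {lr.shape} = {expect} (s={s})"
        )
    base = interpolate_upscale(lr, s, kernel)
    mask = hr.mask | base.mask
    vals = np.where(mask, 0.0, hr.values - base.values)
    return RasterBand(vals, mask, hr.pixel_size, hr.band)
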