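"""Radiometric homogenization between sensors by histogram matching.

Two cameras looking at the same field report systematically different
reflectances (different spectral responses, calibration, illumination
handling).  Before fine-sensor imagery can serve as training truth for
downscaling a coarse sensor, its value distribution is matched to the coarse
sensor's: a monotone map built from paired empirical quantiles, estimated on
co-gridded images (typically after aggregating the fine image to the coarse
grid) and then applied to the native fine image.  The map is per band; it
preserves value ranks exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Union

import numpy as np

from .raster import RasterBand

N_QUANTILES_DEFAULT = 256


@dataclass
class MonotoneMapping:
    """Piecewise-linear monotone value transform for one band.

    ``source_quantiles[i] -> reference_quantiles[i]`` at evenly spaced
    probability levels; between knots the map interpolates linearly, beyond
    the observed source range it extrapolates linearly from the end segments
    (clamping would pile values up into artificial histogram spikes).
    """

    source_quantiles: np.ndarray
    reference_quantiles: np.ndarray
    band: str

    def __post_init__(self) -> None:
        self.source_quantiles = np.asarray(self.source_quantiles, dtype=float)
        self.reference_quantiles = np.asarray(self.reference_quantiles, dtype=float)
        sq, rq = self.source_quantiles, self.reference_quantiles
        if sq.ndim != 1 or sq.shape != rq.shape or sq.size < 2:
            raise ValueError("quantile vectors must be equal-length 1-D with >= 2 entries")
        if np.any(np.diff(sq) < 0) or np.any(np.diff(rq) < 0):
            raise ValueError("quantile vectors must be non-decreasing")

    def __call__(self, v: np.ndarray) -> np.ndarray:
        """Map values; monotone by construction (a <= b implies map(a) <= map(b))."""
        v = np.asarray(v, dtype=float)
        sq, rq = self.source_quantiles, self.reference_quantiles
        out = np.interp(v, sq, rq)
        # linear extrapolation from the end segments
        lo_slope = _end_slope(sq, rq, head=True)
        hi_slope = _end_slope(sq, rq, head=False)
        below = v < sq[0]
        above = v > sq[-1]
        out = np.where(below, rq[0] + (v - sq[0]) * lo_slope, out)
        out = np.where(above, rq[-1] + (v - sq[-1]) * hi_slope, out)
        return out

    def save(self, path: Union[str, os.PathLike]) -> None:
        """Two-column text file (source_quantile, reference_quantile) for audit."""
        header = f"band={self.band}\nsource_quantile\treference_quantile"
        np.savetxt(path, np.column_stack([self.source_quantiles, self.reference_quantiles]),
                   header=header, delimiter="\t")

    @classmethod
    def load(cls, path: Union[str, os.PathLike]) -> "MonotoneMapping":
        band = "red"
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "band=" in line:
                    band = line.split("band=")[1].strip()
                    break
        arr = np.loadtxt(path, delimiter="\t")
        return cls(arr[:, 0], arr[:, 1], band)


def _end_slope(sq: np.ndarray, rq: np.ndarray, head: bool) -> float:
    idx = slice(0, 2) if head else slice(-2, None)
    ds = np.diff(sq[idx])[0]
    dr = np.diff(rq[idx])[0]
    if ds <= 0:
        return 1.0  # degenerate flat end segment: continue with unit slope
    return dr / ds


def estimate_histogram_mapping(
    source: RasterBand, reference: RasterBand, n_quantiles: int = N_QUANTILES_DEFAULT
) -> MonotoneMapping:
    """Match *source*'s value distribution to *reference*'s.

    Both bands must be on the same grid and supply at least ``n_quantiles``
    valid cells each; quantiles are taken at ``n_quantiles`` evenly spaced
    probability levels over valid cells only.
    """
    if source.shape != reference.shape:
        raise ValueError(f"grids differ: source {source.shape}, reference {reference.shape}")
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    sv, rv = source.valid_values(), reference.valid_values()
    for name, v in (("source", sv), ("reference", rv)):
        if v.size < n_quantiles:
            raise ValueError(
                f"{name} has {v.size} valid cells; at least {n_quantiles} required"
            )
    probs = np.linspace(0.0, 1.0, n_quantiles)
    sq = np.quantile(sv, probs)
    rq = np.quantile(rv, probs)
    return MonotoneMapping(sq, rq, source.band)


def apply_mapping(band: RasterBand, mapping: MonotoneMapping) -> RasterBand:
    """Transform every valid cell through the mapping; mask is unchanged.

    The mapping may have been estimated at a coarser (aggregated) grid and is
    routinely applied at the native fine grid.
    """
    if band.band != mapping.band:
        raise ValueError(f"band {band.band!r} does not match mapping band {mapping.band!r}")
    out = band.copy()
    out.values[~out.mask] = mapping(out.values[~out.mask])
    return out
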