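"""Agricultural derivatives of spectral bands.

NDVI — the normalized difference vegetation index,
``(NIR - Red) / (NIR + Red)`` — is the direct product computed here; it is
dimensionless, lies in [-1, 1] for nonnegative reflectances, and is
invariant to a common positive scaling of both bands.  Indirect products
(e.g. externally published surface-soil-moisture retrieval models) plug in
through :func:`register_product` as callables mapping a Scene to an
IndexBand; none ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict

import numpy as np

from .raster import RasterBand, Scene

NDVI_EPSILON = 1e-9


@dataclass
class IndexBand:
    """A dimensionless per-cell index with its own validity mask."""

    values: np.ndarray
    mask: np.ndarray
    index_name: str = "ndvi"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    def valid_values(self) -> np.ndarray:
        return self.values[~self.mask]


def ndvi(red: RasterBand, nir: RasterBand, epsilon: float = NDVI_EPSILON) -> IndexBand:
    """Per-cell ``(NIR - Red) / (NIR + Red)``.

    Cells where the denominator is ``<= epsilon`` (bare of signal) or where
    either input is masked are masked, so the division is never non-finite.
    """
    if red.shape != nir.shape:
        raise ValueError(f"red {red.shape} and nir {nir.shape} are not co-gridded")
    denom = nir.values + red.values
    mask = red.mask | nir.mask | (denom <= epsilon)
    vals = np.zeros(denom.shape)
    np.divide(nir.values - red.values, denom, out=vals, where=~mask)
    return IndexBand(vals, mask, "ndvi")


# -- pluggable indirect products -------------------------------------------

ProductFn = Callable[[Scene], IndexBand]
_PRODUCTS: Dict[str, ProductFn] = {}


def register_product(name: str, fn: ProductFn) -> None:
    """Register an external Scene -> IndexBand model under a product name."""
    _PRODUCTS[name] = fn


def compute_product(name: str, scene: Scene) -> IndexBand:
    if name == "ndvi":
        return ndvi(scene.bands["red"], scene.bands["nir"])
    if name not in _PRODUCTS:
        raise KeyError(f"no product {name!r} registered (built-in: ndvi)")
    return _PRODUCTS[name](scene)
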