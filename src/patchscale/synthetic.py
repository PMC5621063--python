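"""Seeded generator of coincident coarse/fine multispectral scene pairs.

Emulates the study setting of a coarse satellite and a fine aircraft camera
flying over irrigated farmland: circular center-pivot fields (raised NIR and
suppressed red inside each disk, so vegetation NDVI exceeds the
surroundings by construction), a smooth soil background, and spatially
correlated high-frequency texture that exists only at the fine scale — the
content the downscaler is supposed to recover.  The texture field is
generated once per scene and shared across bands with band-specific gains,
which gives the five bands the geometric similarity the coupled-dictionary
method relies on.

Three products per scene: the latent truth ``hr_true``; the fine platform's
measurement ``hr_sensor = gain * hr_true + offset + noise`` (the optional
gain/offset emulates inter-sensor radiometric bias, to exercise the
histogram-matching step); and the coarse platform ``lr_sensor =
block_aggregate(hr_true, s) + noise`` (the bias-free baseline).  The same
seed always yields bit-identical scenes.

Reflectance bands live in [0, 1]; the thermal band is generated in
kelvin-like units (vegetated disks run cooler than bare soil) to exercise
non-reflectance value ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .raster import RasterBand, Scene, block_aggregate

logger = logging.getLogger(__name__)

#: per-band mean bare-soil background (reflectance; thermal in kelvin)
_BACKGROUND = {"red": 0.20, "green": 0.18, "blue": 0.12, "nir": 0.30, "thermal": 312.0}
#: vegetated-canopy minus bare-soil reflectance inside a pivot disk
#: (chlorophyll absorbs blue and red, green is intermediate, NIR is bright,
#: transpiring canopy runs cooler than soil)
_PIVOT_DELTA = {"red": -0.15, "green": -0.08, "blue": -0.07, "nir": 0.20, "thermal": -12.0}
#: band gain applied to the shared unit-variance texture field
_TEXTURE_GAIN = {"red": 1.0, "green": 0.9, "blue": 0.8, "nir": 1.2, "thermal": 60.0}
#: amplitude of the smooth background undulation relative to texture units
_BACKGROUND_GAIN = {"red": 0.6, "green": 0.6, "blue": 0.5, "nir": 0.8, "thermal": 40.0}


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene-pair draw.

    ``texture_amplitude`` is the standard deviation of the fine-scale
    texture in reflectance units (the thermal band scales it into kelvin);
    ``texture_correlation`` its spatial correlation length in fine-grid
    cells; ``bias`` the (gain, offset) of the fine platform relative to the
    latent truth; ``noise_sd`` the per-band additive sensor noise.
    """

    hr_shape: Tuple[int, int] = (128, 128)
    s: int = 2
    n_pivots: int = 3
    texture_amplitude: float = 0.03
    texture_correlation: float = 3.0
    bias: Tuple[float, float] = (1.0, 0.0)
    noise_sd: float = 0.002
    seed: int = 0
    bands: Tuple[str, ...] = ("red", "green", "blue", "nir", "thermal")

    def __post_init__(self) -> None:
        r, c = self.hr_shape
        if r % self.s or c % self.s:
            raise ValueError(f"hr_shape {self.hr_shape} not divisible by s={self.s}")
        if min(self.texture_amplitude, self.noise_sd, self.texture_correlation) < 0:
            raise ValueError("amplitudes and correlation length must be >= 0")
        if self.n_pivots < 0:
            raise ValueError("n_pivots must be >= 0")


def _correlated_field(rng: np.random.Generator, shape, corr: float) -> np.ndarray:
    """Zero-mean, unit-variance Gaussian random field with correlation
    length ~corr cells (Gaussian-filtered white noise, renormalized)."""
    w = rng.standard_normal(shape)
    if corr > 0:
        w = ndimage.gaussian_filter(w, sigma=corr, mode="wrap")
    sd = w.std()
    return w / sd if sd > 0 else w


def generate_scene_pair(spec: SceneSpec) -> Tuple[Scene, Scene, Scene]:
    """Draw one (hr_true, hr_sensor, lr_sensor) triple from the spec."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.hr_shape

    # pivot disks: random centers, radii 15-30% of the short axis
    yy, xx = np.mgrid[0:rows, 0:cols]
    inside = np.zeros(spec.hr_shape, dtype=bool)
    short = min(rows, cols)
    for _ in range(spec.n_pivots):
        cy = rng.uniform(0.15 * rows, 0.85 * rows)
        cx = rng.uniform(0.15 * cols, 0.85 * cols)
        rad = rng.uniform(0.15 * short, 0.30 * short)
        inside |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad ** 2

    background = _correlated_field(rng, spec.hr_shape, 0.15 * short)
    texture = _correlated_field(rng, spec.hr_shape, spec.texture_correlation)

    gain, offset = spec.bias
    hr_true: Dict[str, RasterBand] = {}
    hr_sensor: Dict[str, RasterBand] = {}
    lr_sensor: Dict[str, RasterBand] = {}
    for band in spec.bands:
        unit = _TEXTURE_GAIN[band]  # reflectance bands ~1; thermal scales into K
        latent = (
            _BACKGROUND[band]
            + inside * _PIVOT_DELTA[band]
            + spec.texture_amplitude * _BACKGROUND_GAIN[band] * background
            + spec.texture_amplitude * unit * texture
        )
        if band != "thermal":
            n_clip = int(np.sum((latent < 0) | (latent > 1)))
            if n_clip:
                logger.info(
                    "generate_scene_pair: clipping %.3g%% of %s cells into [0,1]",
                    100.0 * n_clip / latent.size, band,
                )
            latent = np.clip(latent, 0.0, 1.0)
        truth = RasterBand(latent, None, 1.0, band)
        hr_true[band] = truth

        band_noise_sd = spec.noise_sd * (unit if band == "thermal" else 1.0)
        band_offset = offset * (unit if band == "thermal" else 1.0)

        fine = gain * latent + band_offset + band_noise_sd * rng.standard_normal(latent.shape)
        if band != "thermal":
            fine = np.clip(fine, 0.0, 1.0)
        hr_sensor[band] = RasterBand(fine, None, 1.0, band)

        coarse = block_aggregate(truth, spec.s)
        coarse.values = coarse.values + band_noise_sd * rng.standard_normal(coarse.shape)
        if band != "thermal":
            coarse.values = np.clip(coarse.values, 0.0, 1.0)
        lr_sensor[band] = coarse

    tag = f"seed={spec.seed}"
    return (
        Scene(hr_true, acquired=tag, platform="truth"),
        Scene(hr_sensor, acquired=tag, platform="fine-sensor"),
        Scene(lr_sensor, acquired=tag, platform="coarse-sensor"),
    )


def degrade(
    hr: RasterBand,
    s: int,
    psf: str = "box",
    noise_sd: float = 0.0,
    seed: int = 0,
    sigma: float = 0.5,
) -> RasterBand:
    """Simulate a coarse sensor: PSF-weighted aggregation plus noise.

    ``psf='box'`` is the ideal block mean; ``psf='gaussian'`` weights the
    fine cells of each coarse footprint by a Gaussian of standard deviation
    ``sigma`` coarse pixels centered on the block center (edge-clamped at
    image borders, weights normalized to 1).
    """
    if hr.shape[0] % s or hr.shape[1] % s:
        raise ValueError(f"shape {hr.shape} not divisible by s={s}")
    if psf == "box":
        out = block_aggregate(hr, s)
    elif psf == "gaussian":
        out = _gaussian_psf_aggregate(hr, s, sigma)
    else:
        raise ValueError(f"unknown psf {psf!r}; expected 'box' or 'gaussian'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out.values = out.values + noise_sd * rng.standard_normal(out.shape)
    return out


def _gaussian_psf_aggregate(hr: RasterBand, s: int, sigma: float) -> RasterBand:
    sig = sigma * s  # in fine cells
    radius = max(int(np.ceil(4 * sig)), s)
    center = (s - 1) / 2.0
    offsets = np.arange(-radius, radius + s)  # relative to block origin
    w1 = np.exp(-((offsets - center) ** 2) / (2 * sig ** 2))
    kernel = np.outer(w1, w1)
    kernel /= kernel.sum()

    rows, cols = hr.shape
    m, n = rows // s, cols // s
    pad = radius
    vals = np.pad(hr.values, pad, mode="edge")
    acc = np.zeros((m, n))
    for i, du in enumerate(offsets):
        for j, dv in enumerate(offsets):
            block = vals[pad + du : pad + du + rows : s, pad + dv : pad + dv + cols : s]
            acc += kernel[i, j] * block
    mask = block_aggregate(RasterBand(np.ones(hr.shape), hr.mask, 1.0, hr.band), s).mask \
        if hr.mask.any() else np.zeros((m, n), dtype=bool)
    return RasterBand(acc, mask, hr.pixel_size * s, hr.band)
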