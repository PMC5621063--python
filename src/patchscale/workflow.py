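"""Configuration-driven end-to-end experiments.

Reproduces the full experimental design around the downscaler: radiometric
de-biasing of the fine sensor against the coarse sensor, coupled-dictionary
training, per-band downscaling, NDVI derivation, and RMSE scoring against
the aggregated fine-sensor benchmark — under either of two training designs:

* scenario 1 — every available coincident pair populates the dictionary and
  each pair is then scored (the test image is *inside* the training set);
* scenario 2 — leave-one-out: one date is held out, the dictionary is built
  from the remaining pairs, and only the held-out date is scored.

Benchmarks live on the downscaled grid: the (de-biased) fine image is block
aggregated down to ``s x`` the coarse grid before training and scoring.
Cells masked in any input stay masked throughout; no gap-filling happens.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import io
from .debias import estimate_histogram_mapping, apply_mapping, N_QUANTILES_DEFAULT
from .downscale import DownscaleConfig, downscale_band
from .evaluate import EvalReport, evaluate_downscaling, rmse
from .patches import CoupledDictionary, build_coupled_dictionary
from .products import ndvi
from .raster import RasterBand, Scene, block_aggregate, interpolate_upscale

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised on contract violations in an ExperimentConfig (exit code 2)."""


@dataclass
class ScenePair:
    lr_path: str
    hr_path: str
    date: str


@dataclass
class ExperimentConfig:
    """Everything one experiment run needs.

    ``pairs`` lists coincident (coarse scene, fine scene) GeoTIFFs with a
    date tag; ``scenario`` selects the training design (2 requires
    ``held_out`` to name one of the dates); ``bands`` restricts processing
    to a subset of labels (default: every band present in the first pair).
    """

    pairs: List[ScenePair]
    scenario: int = 1
    held_out: Optional[str] = None
    bands: Optional[List[str]] = None
    downscale: DownscaleConfig = field(default_factory=DownscaleConfig)
    debias: bool = True
    n_quantiles: int = N_QUANTILES_DEFAULT
    outputs: Optional[str] = None

    def validate(self) -> None:
        if not self.pairs:
            raise ConfigError("at least one scene pair is required")
        dates = [p.date for p in self.pairs]
        if len(set(dates)) != len(dates):
            raise ConfigError(f"duplicate date tags: {dates}")
        if self.scenario not in (1, 2):
            raise ConfigError(f"scenario must be 1 or 2, got {self.scenario}")
        if self.scenario == 2:
            if self.held_out is None:
                raise ConfigError("scenario 2 requires held_out to name a pair")
            if self.held_out not in dates:
                raise ConfigError(
                    f"held_out {self.held_out!r} is not among the pair dates {dates}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        try:
            pairs = [ScenePair(p["lr"], p["hr"], p["date"]) for p in d["pairs"]]
            ds = DownscaleConfig(**d.get("downscale", {}))
            return cls(
                pairs=pairs,
                scenario=d.get("scenario", 1),
                held_out=d.get("held_out"),
                bands=d.get("bands"),
                downscale=ds,
                debias=d.get("debias", True),
                n_quantiles=d.get("n_quantiles", N_QUANTILES_DEFAULT),
                outputs=d.get("outputs"),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed experiment config: {exc}") from exc


@dataclass
class _PreparedPair:
    date: str
    lr: Scene
    benchmark: Scene  # de-biased fine scene on the downscaled (s x coarse) grid


def _prepare_pair(
    pair: ScenePair, cfg: ExperimentConfig, bands: Sequence[str]
) -> _PreparedPair:
    """De-bias the fine scene against its coarse scene and aggregate it to
    the downscaled grid."""
    lr_scene = io.read_scene(pair.lr_path)
    hr_scene = io.read_scene(pair.hr_path)
    s = cfg.downscale.s
    lr_shape = lr_scene.shape
    hr_shape = hr_scene.shape
    if hr_shape[0] % lr_shape[0] or hr_shape[1] % lr_shape[1]:
        raise ValueError(
            f"{pair.date}: fine shape {hr_shape} is not a multiple of coarse {lr_shape}"
        )
    agg_total = hr_shape[0] // lr_shape[0]
    if hr_shape[1] // lr_shape[1] != agg_total:
        raise ValueError(f"{pair.date}: anisotropic shape ratio between platforms")
    if agg_total % s:
        raise ValueError(
            f"{pair.date}: fine/coarse factor {agg_total} not divisible by s={s}"
        )
    bench_factor = agg_total // s

    bench_bands: Dict[str, RasterBand] = {}
    for label in bands:
        hr_band = hr_scene.bands[label]
        if cfg.debias:
            # estimate the monotone map at the aggregated coarse scale,
            # apply it at the native fine scale
            hr_at_lr = block_aggregate(hr_band, agg_total) if agg_total > 1 else hr_band
            mapping = estimate_histogram_mapping(
                hr_at_lr, lr_scene.bands[label], cfg.n_quantiles
            )
            hr_band = apply_mapping(hr_band, mapping)
        bench_bands[label] = (
            block_aggregate(hr_band, bench_factor) if bench_factor > 1 else hr_band
        )
    benchmark = Scene(bench_bands, acquired=pair.date, platform="benchmark")
    lr_sub = Scene({b: lr_scene.bands[b] for b in bands}, pair.date, lr_scene.platform)
    return _PreparedPair(pair.date, lr_sub, benchmark)


def run_experiment(cfg: ExperimentConfig) -> Dict[Tuple[str, str], EvalReport]:
    """Run the configured experiment; returns reports keyed by (band, date).

    NDVI (when both red and NIR are processed) is scored like a band, under
    the key ``("ndvi", date)``.  When ``cfg.outputs`` is set, downscaled
    scenes and a JSON summary are written there.
    """
    cfg.validate()
    first = io.read_scene(cfg.pairs[0].lr_path)
    bands = cfg.bands if cfg.bands is not None else list(first.bands)
    missing = [b for b in bands if b not in first.bands]
    if missing:
        raise ConfigError(f"requested bands not in input scenes: {missing}")

    prepared = []
    for pair in cfg.pairs:
        t0 = time.time()
        prepared.append(_prepare_pair(pair, cfg, bands))
        logger.info("prepared pair %s in %.2fs", pair.date, time.time() - t0)

    if cfg.scenario == 1:
        train = {p.date: prepared for p in prepared}
        test = prepared
    else:
        train = {cfg.held_out: [p for p in prepared if p.date != cfg.held_out]}
        test = [p for p in prepared if p.date == cfg.held_out]

    s = cfg.downscale.s
    outdir = cfg.outputs
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    reports: Dict[Tuple[str, str], EvalReport] = {}
    for tp in test:
        t0 = time.time()
        dicts: Dict[str, CoupledDictionary] = {}
        for label in bands:
            training_pairs = [
                (p.lr.bands[label], p.benchmark.bands[label]) for p in train[tp.date]
            ]
            dicts[label] = build_coupled_dictionary(
                training_pairs, s, cfg.downscale.patch_edge,
                stride=cfg.downscale.stride, kernel=cfg.downscale.kernel,
            )
        down_bands: Dict[str, RasterBand] = {}
        for label in bands:
            down_bands[label] = downscale_band(tp.lr.bands[label], dicts[label], cfg.downscale)
            reports[(label, tp.date)] = evaluate_downscaling(
                down_bands[label], tp.lr.bands[label], tp.benchmark.bands[label],
                s, cfg.downscale.kernel, cfg.scenario,
            )
        if "red" in bands and "nir" in bands:
            reports[("ndvi", tp.date)] = _ndvi_report(tp, down_bands, s, cfg)
        logger.info("downscaled + scored %s in %.2fs", tp.date, time.time() - t0)

        if outdir:
            down_scene = Scene(down_bands, acquired=tp.date, platform="downscaled")
            io.write_scene(down_scene, os.path.join(outdir, f"downscaled_{tp.date}.tif"))

    if outdir:
        summary = {
            f"{band}/{date}": asdict(rep) for (band, date), rep in reports.items()
        }
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
    return reports


def _ndvi_report(
    tp: _PreparedPair, down_bands: Dict[str, RasterBand], s: int, cfg: ExperimentConfig
) -> EvalReport:
    """Score NDVI derived from downscaled bands against benchmark NDVI,
    with NDVI of the plainly interpolated bands as the baseline."""
    v_down = ndvi(down_bands["red"], down_bands["nir"])
    v_bench = ndvi(tp.benchmark.bands["red"], tp.benchmark.bands["nir"])
    v_base = ndvi(
        interpolate_upscale(tp.lr.bands["red"], s, cfg.downscale.kernel),
        interpolate_upscale(tp.lr.bands["nir"], s, cfg.downscale.kernel),
    )
    valid = ~(v_down.mask | v_bench.mask)
    if not valid.any():
        raise ValueError("no jointly valid NDVI cells")
    rmse_d = float(np.sqrt(np.mean((v_down.values[valid] - v_bench.values[valid]) ** 2)))
    vb = ~(v_base.mask | v_bench.mask)
    rmse_b = float(np.sqrt(np.mean((v_base.values[vb] - v_bench.values[vb]) ** 2)))
    impr = 100.0 * (1.0 - rmse_d / rmse_b) if rmse_b > 0 else 0.0
    return EvalReport(rmse_d, rmse_b, impr, int(valid.sum()), "ndvi", s, cfg.scenario)
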