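"""Quantitative scoring of downscaled products.

The yardstick is the root mean square error against a high-resolution
benchmark (fine imagery aggregated down to the downscaled grid), and the
headline statistic is the *improvement ratio*:

    improvement = 100 * (1 - RMSE_downscaled / RMSE_baseline)   [percent]

where the baseline is plain interpolation of the coarse band scored against
the same benchmark.  0% means the dictionary reconstruction added nothing
over interpolation; 100% means it matched the benchmark exactly; negative
values mean it hurt.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict, dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .raster import RasterBand, interpolate_upscale


@dataclass
class EvalReport:
    """RMSE of the downscaled product and of the interpolation baseline,
    both against the aggregated high-resolution benchmark, plus the percent
    improvement ratio over ``n_cells`` jointly valid cells."""

    rmse_downscaled: float
    rmse_baseline: float
    improvement_ratio: float
    n_cells: int
    band: str
    s: int
    scenario: int = 1

    def to_json(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def rmse(a: RasterBand, b: RasterBand) -> float:
    """Root mean square difference over jointly valid cells."""
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    valid = ~(a.mask | b.mask)
    if not valid.any():
        raise ValueError("no jointly valid cells to compare")
    d = a.values[valid] - b.values[valid]
    return float(np.sqrt(np.mean(d * d)))


def evaluate_downscaling(
    downscaled: RasterBand,
    lr: RasterBand,
    benchmark_hr: RasterBand,
    s: int,
    kernel: str = "bicubic",
    scenario: int = 1,
    scatter_csv: Optional[Union[str, os.PathLike]] = None,
) -> EvalReport:
    """Score a downscaled band against the benchmark on the same grid.

    The caller is responsible for aggregating finer truth imagery onto the
    downscaled grid first.  When ``scatter_csv`` is given, the paired valid
    pixel samples (benchmark, downscaled) are exported as a two-column CSV
    for scatter plotting.
    """
    if downscaled.shape != benchmark_hr.shape:
        raise ValueError(
            f"grid mismatch: downscaled {downscaled.shape} vs benchmark {benchmark_hr.shape}"
        )
    baseline = interpolate_upscale(lr, s, kernel)
    if baseline.shape != benchmark_hr.shape:
        raise ValueError(
            f"grid mismatch: interpolated baseline {baseline.shape} vs "
            f"benchmark {benchmark_hr.shape} (s={s})"
        )
    rmse_d = rmse(downscaled, benchmark_hr)
    rmse_b = rmse(baseline, benchmark_hr)
    improvement = 100.0 * (1.0 - rmse_d / rmse_b) if rmse_b > 0 else 0.0
    valid = ~(downscaled.mask | benchmark_hr.mask)

    if scatter_csv is not None:
        with open(scatter_csv, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["benchmark", "downscaled"])
            w.writerows(zip(benchmark_hr.values[valid], downscaled.values[valid]))

    return EvalReport(
        rmse_downscaled=rmse_d,
        rmse_baseline=rmse_b,
        improvement_ratio=improvement,
        n_cells=int(valid.sum()),
        band=downscaled.band,
        s=s,
        scenario=scenario,
    )
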