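"""Radiometric de-biasing and NDVI derivation.

The fine platform carries a gain/offset bias relative to the coarse
reference. Histogram matching estimated at the aggregated scale and applied
at native scale removes most of the inter-sensor RMSE; NDVI from the
de-biased bands then separates vegetated pivots from bare soil.
"""

import numpy as np

from patchscale import (
    SceneSpec,
    apply_mapping,
    block_aggregate,
    estimate_histogram_mapping,
    generate_scene_pair,
    ndvi,
    rmse,
)

spec = SceneSpec(hr_shape=(128, 128), s=2, bias=(1.1, 0.02), seed=7)
truth, fine, coarse = generate_scene_pair(spec)

for band in ("red", "nir"):
    biased, ref = fine.bands[band], coarse.bands[band]
    aggregated = block_aggregate(biased, 2)
    mapping = estimate_histogram_mapping(aggregated, ref, n_quantiles=256)
    corrected = apply_mapping(biased, mapping)
    print(f"{band:4s} RMSE vs coarse reference: "
          f"{rmse(aggregated, ref):.4f} biased -> "
          f"{rmse(block_aggregate(corrected, 2), ref):.4f} de-biased")
    fine.bands[band] = corrected

v = ndvi(fine.bands["red"], fine.bands["nir"])
nir = truth.bands["nir"].values
inside = nir > np.median(nir) + 0.05  # pivot footprint from the NIR uplift
print(f"NDVI inside pivots:  {v.values[inside].mean():.3f}")
print(f"NDVI outside pivots: {v.values[~inside].mean():.3f}")
# Vegetated center pivots are greener (higher NDVI) than the surrounding
# soil; the de-biased RMSE is an order of magnitude below the biased one.
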