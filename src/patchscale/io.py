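"""GeoTIFF input/output for single bands and scenes.

Files are plain single- or multi-page TIFFs carrying the standard GeoTIFF
georeferencing tags — ``ModelPixelScale`` (33550) for the ground sample
distance, ``ModelTiepoint`` (33922) for the origin — plus the GDAL nodata
convention (ASCII tag 42113).  Band label and value kind travel in a small
JSON ``ImageDescription`` so a file round-trips to an identical
:class:`~patchscale.raster.RasterBand`.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Optional, Union

import numpy as np
import tifffile

from .raster import BAND_LABELS, RasterBand, Scene

NODATA_DEFAULT = -9999.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_band(band: RasterBand, path: Union[str, os.PathLike], nodata: float = NODATA_DEFAULT) -> None:
    """Write one band as a GeoTIFF page with nodata tag and pixel scale."""
    parent = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(parent):
        raise IOError(f"cannot write {path}: directory {parent!r} does not exist")
    data = np.where(band.mask, nodata, band.values).astype(np.float64)
    desc = json.dumps({"band": band.band})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(band.pixel_size), float(band.pixel_size), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, description=desc, extratags=extratags)


def read_band(path: Union[str, os.PathLike], band: Union[int, str] = 0) -> RasterBand:
    """Read one band of a GeoTIFF.

    ``band`` selects a page by 0-based index, or by label when the file was
    written by this package (label stored in the page description).  Values
    equal to the file's nodata tag are masked.
    """
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = tif.pages
        n = len(pages)
        if isinstance(band, str):
            idx = None
            for i in range(n):
                if _page_label(pages[i]) == band:
                    idx = i
                    break
            if idx is None:
                raise ValueError(f"{path}: no page labelled {band!r} among {n} page(s)")
        else:
            idx = int(band)
            if not (0 <= idx < n):
                raise ValueError(f"{path}: band index {idx} out of range for {n} page(s)")
        page = pages[idx]
        values = page.asarray().astype(np.float64)
        if values.ndim != 2:
            raise ValueError(f"{path}: page {idx} is not a 2-D raster")

        tags = page.tags
        if _TAG_PIXEL_SCALE in tags:
            pixel_size = float(tags[_TAG_PIXEL_SCALE].value[0])
        else:
            raise IOError(f"{path}: missing geotransform (no ModelPixelScale tag)")
        mask = np.zeros(values.shape, dtype=bool)
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
            mask = values == nodata
        label = _page_label(page) or "red"
    return RasterBand(np.where(mask, 0.0, values), mask, pixel_size, label)


def _page_label(page) -> Optional[str]:
    desc = page.description
    if desc:
        try:
            meta = json.loads(desc)
            if isinstance(meta, dict) and meta.get("band") in BAND_LABELS:
                return meta["band"]
        except (ValueError, TypeError):
            pass
    return None


def write_scene(scene: Scene, path: Union[str, os.PathLike], nodata: float = NODATA_DEFAULT) -> None:
    """Write all bands of a scene as labelled pages of one multi-page GeoTIFF."""
    parent = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(parent):
        raise IOError(f"cannot write {path}: directory {parent!r} does not exist")
    px = scene.pixel_size
    with tifffile.TiffWriter(path) as tw:
        for label, band in scene.bands.items():
            data = np.where(band.mask, nodata, band.values).astype(np.float64)
            desc = json.dumps({"band": label, "acquired": scene.acquired, "platform": scene.platform})
            extratags = [
                (_TAG_PIXEL_SCALE, "d", 3, (float(px), float(px), 0.0)),
                (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
                (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
            ]
            tw.write(data, description=desc, extratags=extratags)


def read_scene(path: Union[str, os.PathLike]) -> Scene:
    """Read a multi-page GeoTIFF written by :func:`write_scene`."""
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    bands: Dict[str, RasterBand] = {}
    acquired = platform = ""
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            label = _page_label(page)
            if label is None:
                raise ValueError(f"{path}: page {i} carries no band label")
            desc = json.loads(page.description)
            acquired = desc.get("acquired", "")
            platform = desc.get("platform", "")
            bands[label] = read_band(path, i)
            bands[label].band = label
    return Scene(bands, acquired=acquired, platform=platform)
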