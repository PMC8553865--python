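"""Raster application of the per-pixel algorithm: masking, maps, upscaling.

GeoTIFF reading and writing is done with tifffile; georeferencing is carried
by the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, a minimal
GeoKeyDirectory declaring the CRS by EPSG code) plus the GDAL nodata tag.
Only north-up grids are handled — reprojection is out of scope.

Output maps are unsigned 8-bit with nodata = 255.  Intensity maps code
0/1/2/3 = none/single/double/triple cropping; QC maps code 0/1/2/3 =
best/good/fair/poor.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile

from .classify import classify_aligned, classify_pixel_year
from .evi import (
    AlgorithmConfig,
    EviSeries,
    FitError,
    InsufficientDataError,
    BoundaryYearError,
)
from .simulate import NODATA, SyntheticScene

__all__ = [
    "GeoRef",
    "IntensityMap",
    "QcMap",
    "apply_cropland_mask",
    "compute_intensity_maps",
    "compute_intensity_maps_from_arrays",
    "difference_map",
    "read_evi_stack",
    "read_geotiff",
    "read_map",
    "upscale_intensity",
    "write_geotiff",
    "write_map",
    "write_scene",
]

logger = logging.getLogger(__name__)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GeoRef:
    """North-up georeferencing: top-left corner, pixel size, EPSG code."""

    x0: float = 0.0
    y0: float = 0.0
    px: float = 1.0
    py: float = 1.0  # positive; rows run southward
    epsg: int = 4326

    def scaled(self, factor: int) -> "GeoRef":
        return GeoRef(self.x0, self.y0, self.px * factor, self.py * factor, self.epsg)


def write_geotiff(path, array: np.ndarray, georef: GeoRef = GeoRef(), nodata=None) -> None:
    """Write a single-band north-up GeoTIFF (uncompressed, strip-per-block)."""
    # GTModelTypeGeoKey=2 (geographic) for EPSG:4326, else 1 (projected);
    # GTRasterTypeGeoKey=1 (PixelIsArea); Geographic/ProjectedTypeGeoKey=EPSG.
    model_type = 2 if georef.epsg == 4326 else 1
    crs_key = 2048 if model_type == 2 else 3072
    geokeys = (1, 1, 0, 3, 1024, 0, 1, model_type, 1025, 0, 1, 1, crs_key, 0, 1, georef.epsg)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (georef.px, georef.py, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, georef.x0, georef.y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(geokeys), geokeys),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(path, array, extratags=extratags, photometric="minisblack")


def read_geotiff(path) -> tuple[np.ndarray, GeoRef, float | None]:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        array = page.asarray()
        tags = page.tags
        georef = GeoRef()
        if _TAG_PIXEL_SCALE in tags and _TAG_TIEPOINT in tags:
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            tp = tags[_TAG_TIEPOINT].value
            epsg = 4326
            if _TAG_GEO_KEYS in tags:
                keys = tags[_TAG_GEO_KEYS].value
                for i in range(4, len(keys) - 3, 4):
                    if keys[i] in (2048, 3072):
                        epsg = int(keys[i + 3])
            georef = GeoRef(x0=float(tp[3]), y0=float(tp[4]), px=float(sx), py=float(sy), epsg=epsg)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    return array, georef, nodata


@dataclass
class IntensityMap:
    """Grid of cropping-intensity codes {0..3}, nodata=255, georeferenced."""

    data: np.ndarray
    georef: GeoRef
    year: int
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        valid = self.data[self.data != self.nodata]
        if valid.size and valid.max() > 3:
            raise ValueError("intensity codes must be in {0,1,2,3} or nodata")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata


class QcMap(IntensityMap):
    """Grid of quality codes {0..3} = best/good/fair/poor, nodata=255."""


def write_map(path, m: IntensityMap) -> None:
    write_geotiff(path, m.data, m.georef, nodata=m.nodata)


def read_map(path, year: int = 0, cls=IntensityMap) -> IntensityMap:
    array, georef, nodata = read_geotiff(path)
    return cls(data=array, georef=georef, year=year, nodata=int(nodata) if nodata is not None else NODATA)


_DATE_PATTERNS = (re.compile(r"(\d{4})-(\d{2})-(\d{2})"), re.compile(r"(\d{4})(\d{3})(?!\d)"))


def _dates_for(paths: list[Path]) -> list[dt.date]:
    """Composite dates from a dates.json sidecar, else from filenames."""
    sidecar = paths[0].parent / "dates.json"
    if sidecar.exists():
        with open(sidecar) as fh:
            dates = [dt.date.fromisoformat(s) for s in json.load(fh)]
        if len(dates) != len(paths):
            raise ValueError("dates.json length does not match raster count")
        return dates
    dates = []
    for p in paths:
        m = _DATE_PATTERNS[0].search(p.name)
        if m:
            dates.append(dt.date(*map(int, m.groups())))
            continue
        m = _DATE_PATTERNS[1].search(p.name)
        if m:
            year, doy = int(m.group(1)), int(m.group(2))
            dates.append(dt.date(year, 1, 1) + dt.timedelta(days=doy - 1))
            continue
        raise ValueError(f"cannot parse a composite date from {p.name}")
    return dates


def _open_stack(paths: list[Path]):
    """Memory-mapped handles to a list of uncompressed single-band rasters."""
    arrays = []
    for p in paths:
        try:
            arrays.append(tifffile.memmap(p))
        except ValueError:  # compressed/tiling layouts: fall back to full read
            arrays.append(tifffile.imread(p))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"rasters do not share one grid: {sorted(shapes)}")
    return arrays


def read_evi_stack(
    evi_paths,
    flag_paths,
    config: AlgorithmConfig | None = None,
    dates: list[dt.date] | None = None,
    block_rows: int = 128,
) -> Iterator[tuple[tuple[int, int], EviSeries]]:
    """Stream per-pixel EVI series from stacks of single-band rasters.

    Rasters are memory-mapped and consumed in row blocks, so peak memory is
    bounded by the block size rather than the scene size.  Raw values are
    multiplied by the configured scale factor; composite dates come from a
    ``dates.json`` sidecar next to the EVI rasters, or from filenames
    (``YYYY-MM-DD`` or ``YYYYDDD``).
    """
    if config is None:
        config = AlgorithmConfig()
    evi_paths = [Path(p) for p in evi_paths]
    flag_paths = [Path(p) for p in flag_paths]
    if len(evi_paths) != len(flag_paths):
        raise ValueError("EVI and flag raster counts differ")
    if dates is None:
        dates = _dates_for(evi_paths)
    epoch = dt.date(dates[0].year, 1, 1)
    times = np.array([(d - epoch).days for d in dates], dtype=np.int64)
    evi_maps = _open_stack(evi_paths)
    flag_maps = _open_stack(flag_paths)
    if evi_maps[0].shape != flag_maps[0].shape:
        raise ValueError("EVI and flag rasters do not share one grid")
    n_rows, n_cols = evi_maps[0].shape
    for r0 in range(0, n_rows, block_rows):
        r1 = min(r0 + block_rows, n_rows)
        evi_block = np.stack([a[r0:r1] for a in evi_maps]).astype(np.float64) * config.evi_scale_factor
        flag_block = np.stack([a[r0:r1] for a in flag_maps])
        for r in range(r1 - r0):
            for c in range(n_cols):
                yield (r0 + r, c), EviSeries(
                    times=times,
                    values=np.clip(evi_block[:, r, c], -0.2, 1.0),
                    flags=flag_block[:, r, c].astype(np.int64),
                    interpolated=np.zeros(len(times), dtype=bool),
                    epoch=epoch,
                )


def apply_cropland_mask(
    map_grid: np.ndarray, prob_raster: np.ndarray, config: AlgorithmConfig | None = None, nodata: int = NODATA
) -> np.ndarray:
    """Set pixels whose cropland probability is not strictly above the
    threshold (default 10%) to nodata."""
    if config is None:
        config = AlgorithmConfig()
    if map_grid.shape != prob_raster.shape:
        raise ValueError("grid and cropland-probability raster are misaligned")
    out = map_grid.copy()
    out[~(prob_raster > config.cropland_prob_threshold)] = nodata
    return out


def compute_intensity_maps_from_arrays(
    evi: np.ndarray,
    flags: np.ndarray,
    dates: list[dt.date],
    cropland_prob: np.ndarray,
    year: int,
    config: AlgorithmConfig | None = None,
    georef: GeoRef = GeoRef(),
) -> tuple[IntensityMap, QcMap]:
    """Per-pixel classification of an in-memory (T, H, W) EVI stack.

    ``evi`` is on the physical scale.  Non-cropland pixels and pixels whose
    series cannot be processed (too few valid observations) come out as
    nodata; a failing pixel never aborts the scene.
    """
    if config is None:
        config = AlgorithmConfig()
    n_t, n_rows, n_cols = evi.shape
    if flags.shape != evi.shape:
        raise ValueError("EVI and flag stacks are misaligned")
    if cropland_prob.shape != (n_rows, n_cols):
        raise ValueError("cropland raster misaligned with the stack")
    if len(dates) != n_t:
        raise ValueError("need one date per layer")
    epoch = dt.date(dates[0].year, 1, 1)
    times = np.array([(d - epoch).days for d in dates], dtype=np.int64)

    intensity = np.full((n_rows, n_cols), NODATA, dtype=np.uint8)
    qc = np.full((n_rows, n_cols), NODATA, dtype=np.uint8)
    cropland = cropland_prob > config.cropland_prob_threshold
    n_err = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if not cropland[r, c]:
                continue
            series = EviSeries(
                times=times,
                values=np.clip(evi[:, r, c], -0.2, 1.0),
                flags=flags[:, r, c].astype(np.int64),
                interpolated=np.zeros(n_t, dtype=bool),
                epoch=epoch,
            )
            try:
                result = classify_pixel_year(series, year, config)
            except (InsufficientDataError, FitError, BoundaryYearError):
                n_err += 1
                continue
            intensity[r, c] = result.intensity
            qc[r, c] = result.qc_code
    n_cropland = int(cropland.sum())
    logger.info(
        "scene %dx%d year %d: %d cropland, %d non-cropland, %d errored",
        n_rows, n_cols, year, n_cropland, n_rows * n_cols - n_cropland, n_err,
    )
    return (
        IntensityMap(data=intensity, georef=georef, year=year),
        QcMap(data=qc, georef=georef, year=year),
    )


def compute_intensity_maps(
    evi_paths,
    flag_paths,
    cropland_path,
    year: int,
    config: AlgorithmConfig | None = None,
    block_rows: int = 128,
) -> tuple[IntensityMap, QcMap]:
    """File-based scene classification, streaming row blocks from disk."""
    if config is None:
        config = AlgorithmConfig()
    prob, georef, _ = read_geotiff(cropland_path)
    intensity = np.full(prob.shape, NODATA, dtype=np.uint8)
    qc = np.full(prob.shape, NODATA, dtype=np.uint8)
    cropland = prob > config.cropland_prob_threshold
    n_err = 0
    for (r, c), series in read_evi_stack(evi_paths, flag_paths, config, block_rows=block_rows):
        if not cropland[r, c]:
            continue
        try:
            result = classify_pixel_year(series, year, config)
        except (InsufficientDataError, FitError, BoundaryYearError):
            n_err += 1
            continue
        intensity[r, c] = result.intensity
        qc[r, c] = result.qc_code
    n_cropland = int(cropland.sum())
    logger.info(
        "scene %s year %d: %d cropland, %d non-cropland, %d errored",
        prob.shape, year, n_cropland, prob.size - n_cropland, n_err,
    )
    return (
        IntensityMap(data=intensity, georef=georef, year=year),
        QcMap(data=qc, georef=georef, year=year),
    )


def upscale_intensity(m: IntensityMap, factor: int) -> IntensityMap:
    """Aggregate to a coarser grid by modal intensity per block.

    Each ``factor x factor`` block maps to the most frequent non-nodata code
    (ties resolve to the lower code, a conservative choice); an all-nodata
    block stays nodata.  Dimensions not divisible by the factor are padded
    with nodata first.
    """
    if factor < 2:
        raise ValueError("factor must be >= 2")
    data = m.data
    h, w = data.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        data = np.pad(data, ((0, ph), (0, pw)), constant_values=m.nodata)
    hh, ww = data.shape[0] // factor, data.shape[1] // factor
    blocks = data.reshape(hh, factor, ww, factor)
    counts = np.stack([(blocks == k).sum(axis=(1, 3)) for k in range(4)])
    out = np.argmax(counts, axis=0).astype(np.uint8)  # argmax takes the lower code on ties
    out[counts.sum(axis=0) == 0] = m.nodata
    return IntensityMap(data=out, georef=m.georef.scaled(factor), year=m.year, nodata=m.nodata)


def difference_map(a: IntensityMap, b: IntensityMap) -> np.ma.MaskedArray:
    """Signed intensity difference a - b (range -3..3), masked off-cropland."""
    if a.data.shape != b.data.shape:
        raise ValueError("maps are misaligned")
    if a.georef != b.georef:
        raise ValueError("maps have different georeferencing")
    valid = a.valid_mask & b.valid_mask
    diff = a.data.astype(np.int16) - b.data.astype(np.int16)
    return np.ma.MaskedArray(diff, mask=~valid)


def write_scene(scene: SyntheticScene, outdir) -> dict:
    """Write a synthetic scene as GeoTIFFs + sidecars; returns the paths."""
    outdir = Path(outdir)
    evi_dir = outdir / "evi"
    flag_dir = outdir / "flags"
    evi_dir.mkdir(parents=True, exist_ok=True)
    flag_dir.mkdir(parents=True, exist_ok=True)
    georef = GeoRef()
    evi_paths, flag_paths = [], []
    for i, date in enumerate(scene.dates):
        p = evi_dir / f"evi_{date.isoformat()}.tif"
        write_geotiff(p, scene.evi_raw[i], georef)
        evi_paths.append(p)
        p = flag_dir / f"flag_{date.isoformat()}.tif"
        write_geotiff(p, scene.flags[i], georef)
        flag_paths.append(p)
    with open(evi_dir / "dates.json", "w") as fh:
        json.dump([d.isoformat() for d in scene.dates], fh)
    cropland = outdir / "cropland_prob.tif"
    write_geotiff(cropland, scene.cropland_prob, georef)
    truth = outdir / "truth.tif"
    write_geotiff(truth, scene.truth, georef, nodata=NODATA)
    with open(outdir / "params.json", "w") as fh:
        json.dump(scene.params, fh, indent=2)
    return {
        "evi": evi_paths,
        "flags": flag_paths,
        "cropland": cropland,
        "truth": truth,
    }
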