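"""Synthetic EVI records and raster scenes with known cropping intensity.

Every module of the package is testable without downloading satellite data.
A pixel-year is emulated as a baseline EVI plus one Gaussian pulse per crop
cycle,

    EVI(t) = baseline + sum_k A_k * exp(-(t - c_k)^2 / (2 w^2)),

with additive Gaussian noise and randomly placed cloud contamination: a
cloudy observation receives an unacceptable reliability flag and a corrupted
low value, mimicking cloud-darkened EVI.  Default season centres keep
adjacent cycles far enough apart that clean pulses always satisfy the
peak-filter thresholds, so the generated label is the pipeline's ground
truth.

Scenes extend this per-pixel model to raster stacks: a class mixture over
intensities 0-3, a cropland-probability layer (non-cropland pixels draw
probabilities below the masking threshold), and a ground-truth map.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .evi import COMPOSITES_PER_YEAR, AlgorithmConfig, EviSeries, composite_times

__all__ = ["DEFAULT_SEASON_CENTERS", "SyntheticParams", "SyntheticScene", "generate_pixel", "generate_scene"]

#: Default per-cycle season centres (day of year).  Adjacent cycles sit more
#: than 90 days apart, so default pulses pass the duration filter.  Triple
#: cropping spreads evenly through the year (365/3 ~ 122-day spacing), as in
#: real triple-rice systems — a degree-6 polynomial can only resolve three
#: maxima when the cycles occupy the whole 12-month window.
DEFAULT_SEASON_CENTERS = {0: (), 1: (200,), 2: (130, 270), 3: (61, 183, 305)}

#: Default Gaussian pulse widths (std, days) by cycle count.  The width must
#: fit the cycle length: harvested fields drop back near the baseline EVI
#: between cycles, so with 122-day-spaced cycles the pulse narrows to 20
#: days (inter-cycle overlap < 0.05 of the amplitude); longer cycles use 30.
DEFAULT_SEASON_WIDTHS = {0: 30.0, 1: 30.0, 2: 30.0, 3: 20.0}

#: Default amplitude draw ranges by cycle count.  Single and double cropping
#: span everything from semi-arid cereals to irrigated systems; triple
#: cropping happens only in intensively managed, irrigated fields whose peak
#: EVI runs high and uniform — and the degree-6 fit attenuates the middle of
#: three peaks strongly, so only such high-amplitude cycles are detectable.
DEFAULT_AMPLITUDE_RANGES = {0: (0.45, 0.80), 1: (0.45, 0.80), 2: (0.45, 0.80), 3: (0.60, 0.80)}

#: Reliability flag written on cloud-contaminated observations.
CLOUDY_FLAG = 3

#: Raster nodata code for intensity/QC/truth maps.
NODATA = 255


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the per-pixel simulator.

    ``peak_amplitudes`` and ``season_centers`` default to None, meaning:
    amplitudes are drawn uniformly in [0.45, 0.80] per cycle, and centres
    come from :data:`DEFAULT_SEASON_CENTERS` for the given cycle count.
    """

    n_cycles: int = 1
    peak_amplitudes: tuple | None = None
    baseline: float = 0.12
    season_centers: tuple | None = None
    season_width_days: float | None = None
    noise_sd: float = 0.02
    cloud_prob: float = 0.10
    start_shift_days: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_cycles <= 3:
            raise ValueError("n_cycles must be in 0..3")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must be a probability")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.season_width_days is not None and self.season_width_days <= 0:
            raise ValueError("season_width_days must be positive")
        if self.peak_amplitudes is not None:
            if len(self.peak_amplitudes) != self.n_cycles:
                raise ValueError("need one amplitude per cycle")
            if self.n_cycles and max(self.peak_amplitudes) + self.baseline > 1.0 + 1e-9:
                raise ValueError("amplitude + baseline must not exceed 1.0")
        if self.season_centers is not None and len(self.season_centers) != self.n_cycles:
            raise ValueError("need one season centre per cycle")

    def resolve(self, rng: np.random.Generator) -> tuple[tuple, tuple, float]:
        """Concrete (amplitudes, centres, width), drawing amplitudes if unset."""
        if self.peak_amplitudes is None:
            lo, hi = DEFAULT_AMPLITUDE_RANGES[self.n_cycles]
            amps = tuple(rng.uniform(lo, hi, size=self.n_cycles))
        else:
            amps = tuple(self.peak_amplitudes)
        centers = self.season_centers
        if centers is None:
            centers = DEFAULT_SEASON_CENTERS[self.n_cycles]
        width = self.season_width_days
        if width is None:
            width = DEFAULT_SEASON_WIDTHS[self.n_cycles]
        return amps, tuple(c + self.start_shift_days for c in centers), width


def _clean_signal(
    times: np.ndarray, year_offsets: np.ndarray, baseline: float, amps, centers, width: float
) -> np.ndarray:
    """Noise-free EVI at absolute day offsets; pulses repeat every year."""
    values = np.full(times.shape, baseline, dtype=float)
    for off in year_offsets:
        for amp, center in zip(amps, centers):
            values += amp * np.exp(-((times - (off + center)) ** 2) / (2.0 * width**2))
    return values


def generate_pixel(
    params: SyntheticParams,
    years: int = 3,
    start_year: int = 2001,
    rng: np.random.Generator | None = None,
) -> tuple[EviSeries, int]:
    """One multi-year pixel record plus its true cycle count.

    ``years >= 3`` so that interior years have the flanking composites the
    18-month analysis window needs.  Identical seeds give identical output.
    """
    if years < 3:
        raise ValueError("need years >= 3 to provide flanking composites")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    epoch = dt.date(start_year, 1, 1)
    times = composite_times(start_year, years, epoch)
    year_offsets = np.array(
        [(dt.date(y, 1, 1) - epoch).days for y in range(start_year, start_year + years)]
    )
    amps, centers, width = params.resolve(rng)
    values = _clean_signal(times, year_offsets, params.baseline, amps, centers, width)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=values.shape)
    cloudy = rng.random(values.shape) < params.cloud_prob
    values[cloudy] = rng.uniform(-0.1, 0.1, size=int(cloudy.sum()))
    values = np.clip(values, -0.2, 1.0)
    flags = np.where(cloudy, CLOUDY_FLAG, 0).astype(np.int64)
    series = EviSeries(
        times=times,
        values=values,
        flags=flags,
        interpolated=np.zeros(values.shape, dtype=bool),
        epoch=epoch,
    )
    return series, params.n_cycles


@dataclass
class SyntheticScene:
    """An in-memory raster scene: EVI stack, flags, cropland probability, truth.

    ``evi_raw`` is int16 on the raw scale (physical EVI / scale factor),
    matching the MOD13Q1 storage convention; ``truth`` holds the intensity
    class for cropland pixels and the nodata code elsewhere.
    """

    dates: list[dt.date]
    evi_raw: np.ndarray  # (T, H, W) int16
    flags: np.ndarray  # (T, H, W) uint8
    cropland_prob: np.ndarray  # (H, W) float32
    truth: np.ndarray  # (H, W) uint8, NODATA outside cropland
    start_year: int
    years: int
    params: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cropland_prob.shape

    def evi_physical(self, scale: float = 1e-4) -> np.ndarray:
        return self.evi_raw.astype(np.float64) * scale


def generate_scene(
    rows: int,
    cols: int,
    class_mix=(0.25, 0.25, 0.25, 0.25),
    years: int = 3,
    start_year: int = 2001,
    template: SyntheticParams | None = None,
    noncropland_frac: float = 0.0,
    seed: int = 0,
    config: AlgorithmConfig | None = None,
) -> SyntheticScene:
    """A raster scene of independently drawn pixels with known truth.

    Cropland pixels draw an intensity class from ``class_mix`` (fractions
    over classes 0-3, summing to 1) and a cropland probability above the
    masking threshold; a ``noncropland_frac`` share of pixels instead gets a
    probability below it (and baseline-only vegetation), so they are masked
    downstream and carry nodata in the truth map.
    """
    if rows <= 0 or cols <= 0:
        raise ValueError("scene must have positive dimensions")
    mix = np.asarray(class_mix, dtype=float)
    if mix.shape != (4,) or abs(mix.sum() - 1.0) > 1e-9 or (mix < 0).any():
        raise ValueError("class_mix must be 4 non-negative fractions summing to 1")
    if not 0.0 <= noncropland_frac <= 1.0:
        raise ValueError("noncropland_frac must be a fraction")
    if template is None:
        template = SyntheticParams()
    if config is None:
        config = AlgorithmConfig()

    rng = np.random.default_rng(seed)
    n_t = years * COMPOSITES_PER_YEAR
    scale = config.evi_scale_factor
    evi_raw = np.empty((n_t, rows, cols), dtype=np.int16)
    flags = np.empty((n_t, rows, cols), dtype=np.uint8)
    prob = np.empty((rows, cols), dtype=np.float32)
    truth = np.empty((rows, cols), dtype=np.uint8)
    thr = config.cropland_prob_threshold

    for r in range(rows):
        for c in range(cols):
            noncrop = rng.random() < noncropland_frac
            if noncrop:
                cls = 0
                prob[r, c] = rng.uniform(0.0, thr * 0.999)
                truth[r, c] = NODATA
            else:
                cls = int(rng.choice(4, p=mix))
                prob[r, c] = rng.uniform(min(2 * thr, 1.0), 1.0)
                truth[r, c] = cls
            params = dataclasses.replace(template, n_cycles=cls)
            series, _ = generate_pixel(params, years=years, start_year=start_year, rng=rng)
            evi_raw[:, r, c] = np.round(series.values / scale).astype(np.int16)
            flags[:, r, c] = series.flags.astype(np.uint8)

    from .evi import composite_dates

    return SyntheticScene(
        dates=composite_dates(start_year, years),
        evi_raw=evi_raw,
        flags=flags,
        cropland_prob=prob,
        truth=truth,
        start_year=start_year,
        years=years,
        params={
            "class_mix": list(mix),
            "noncropland_frac": noncropland_frac,
            "noise_sd": template.noise_sd,
            "cloud_prob": template.cloud_prob,
            "seed": seed,
        },
    )
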