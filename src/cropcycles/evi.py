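"""Core domain types shared across the package, plus the EVI definition.

The enhanced vegetation index (EVI) is a reflectance-based greenness index,
less sensitive to atmospheric and soil background effects than NDVI:

    EVI = 2.5 * (rho_NIR - rho_Red) / (rho_NIR + 6*rho_Red - 7.5*rho_Blue + 1)

All EVI values in this package live on the physical scale (roughly -0.2 to
1.0).  Raw int16 rasters in the MOD13Q1 convention are multiplied by
``AlgorithmConfig.evi_scale_factor`` (1e-4) at I/O time, because every
threshold of the cropping-intensity algorithm (peak amplitude 0.35, minimum
peak-valley depth 0.01) is stated on the physical scale.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "COMPOSITES_PER_YEAR",
    "COMPOSITE_PERIOD_DAYS",
    "DEFAULT_ACCEPTABLE_FLAGS",
    "AlgorithmConfig",
    "AnnualWindow",
    "BoundaryYearError",
    "DegenerateInputError",
    "EviSeries",
    "FitError",
    "InsufficientDataError",
    "ReflectanceSample",
    "composite_dates",
    "composite_times",
    "evi_from_reflectance",
    "read_long_table",
]

#: Number of 16-day composites per calendar year (day-of-year 1, 17, ..., 353).
COMPOSITES_PER_YEAR = 23
#: Nominal spacing of composites in days.
COMPOSITE_PERIOD_DAYS = 16
#: MODIS pixel-reliability codes treated as acceptable by default
#: (0 = good data, 1 = marginal).
DEFAULT_ACCEPTABLE_FLAGS = frozenset({0, 1})


class DegenerateInputError(ValueError):
    """An input is mathematically degenerate (e.g. zero EVI denominator)."""


class InsufficientDataError(ValueError):
    """Too few valid observations to proceed (e.g. < 2 points to interpolate)."""


class BoundaryYearError(ValueError):
    """The record lacks the flanking composites needed for an 18-month window."""


class FitError(ValueError):
    """The polynomial fit could not be computed (rank-deficient design)."""


@dataclass(frozen=True)
class ReflectanceSample:
    """Surface reflectance in the three bands entering the EVI formula.

    Each reflectance is unitless in [0, 1].
    """

    rho_nir: float
    rho_red: float
    rho_blue: float

    def __post_init__(self) -> None:
        for name in ("rho_nir", "rho_red", "rho_blue"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")


def evi_from_reflectance(sample: ReflectanceSample) -> float:
    """Enhanced vegetation index from a reflectance sample.

    Raises
    ------
    DegenerateInputError
        If the denominator ``rho_NIR + 6*rho_Red - 7.5*rho_Blue + 1`` is
        smaller than 1e-12 in magnitude.
    """
    den = sample.rho_nir + 6.0 * sample.rho_red - 7.5 * sample.rho_blue + 1.0
    if abs(den) < 1e-12:
        raise DegenerateInputError("EVI denominator is (near) zero")
    return 2.5 * (sample.rho_nir - sample.rho_red) / den


@dataclass
class EviSeries:
    """A dated EVI sequence with per-observation quality flags.

    Attributes
    ----------
    times
        Observation times as integer days since ``epoch`` (strictly
        increasing, nominally 16-day spacing).
    values
        EVI on the physical scale; NaN marks a missing observation.
    flags
        Integer reliability code per observation.  Which codes count as
        acceptable is decided by the caller (``AlgorithmConfig.acceptable_flags``).
    interpolated
        True where the value was produced by gap filling rather than observed.
    epoch
        Calendar date of day 0 of the time axis.
    """

    times: np.ndarray
    values: np.ndarray
    flags: np.ndarray
    interpolated: np.ndarray
    epoch: dt.date

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.flags = np.asarray(self.flags, dtype=np.int64)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = len(self.times)
        if not (len(self.values) == len(self.flags) == len(self.interpolated) == n):
            raise ValueError("times, values, flags and interpolated must have equal length")
        if n == 0:
            raise ValueError("empty series")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -0.2 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise ValueError("EVI values outside the physical range [-0.2, 1.0]")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dates(self) -> list[dt.date]:
        return [self.epoch + dt.timedelta(days=int(t)) for t in self.times]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def slice(self, start: int, stop: int) -> "EviSeries":
        return EviSeries(
            times=self.times[start:stop],
            values=self.values[start:stop],
            flags=self.flags[start:stop],
            interpolated=self.interpolated[start:stop],
            epoch=self.epoch,
        )

    def with_values(self, values: np.ndarray, interpolated: np.ndarray | None = None) -> "EviSeries":
        return EviSeries(
            times=self.times,
            values=values,
            flags=self.flags,
            interpolated=self.interpolated if interpolated is None else interpolated,
            epoch=self.epoch,
        )


#: Composites flanking the labeled year on each side of the 18-month window
#: ("three months" of 16-day composites: 6 * 16 = 96 days).
WINDOW_FLANK = 6
#: Total composites in the 18-month analysis window.
WINDOW_LENGTH = 2 * WINDOW_FLANK + COMPOSITES_PER_YEAR  # 35


@dataclass
class AnnualWindow:
    """The 18-month (35-composite) analysis window centred on one year.

    Six composites of the previous year, the 23 composites of the labeled
    year, and six composites of the following year.
    """

    year: int
    samples: EviSeries
    core_start: int = WINDOW_FLANK

    def __post_init__(self) -> None:
        if len(self.samples) != WINDOW_LENGTH:
            raise ValueError(f"annual window must hold {WINDOW_LENGTH} composites, got {len(self.samples)}")
        if self.core_start != WINDOW_FLANK:
            raise ValueError(f"core_start must be {WINDOW_FLANK}")


@dataclass(frozen=True)
class AlgorithmConfig:
    """Tunable thresholds of the cropping-intensity algorithm.

    Parameters
    ----------
    peak_min_evi
        A fitted peak must exceed this EVI to count as a crop cycle.
    min_peak_valley_depth
        The peak must rise above its valleys by more than this (EVI units).
    min_peak_valley_duration_days
        Duration threshold ("three months" = 90 days on the day axis).
    duration_rule
        How the duration threshold is applied.  ``"span"`` (default) tests
        the full cycle duration, left valley to right valley; ``"min_side"``
        tests the shorter of the two peak-to-valley intervals.
    depth_rule
        ``"both"`` (default) requires the depth on the shallower side to pass;
        ``"either"`` accepts if either side passes.
    cropland_prob_threshold
        Pixels with cropland probability strictly greater than this are
        treated as cropland.
    evi_scale_factor
        Multiplier turning raw int16 raster values into physical EVI.
    max_intensity
        Cap on the reported number of cycles (a degree-6 fit cannot yield
        more than 3 maxima).
    acceptable_flags
        Reliability codes treated as acceptable observations.
    """

    peak_min_evi: float = 0.35
    min_peak_valley_depth: float = 0.01
    min_peak_valley_duration_days: float = 90.0
    duration_rule: str = "span"
    depth_rule: str = "both"
    cropland_prob_threshold: float = 0.10
    evi_scale_factor: float = 1e-4
    max_intensity: int = 3
    acceptable_flags: frozenset = DEFAULT_ACCEPTABLE_FLAGS

    def __post_init__(self) -> None:
        for name in (
            "peak_min_evi",
            "min_peak_valley_depth",
            "min_peak_valley_duration_days",
            "cropland_prob_threshold",
            "evi_scale_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_intensity != 3:
            raise ValueError("max_intensity must be 3")
        if self.duration_rule not in ("span", "min_side"):
            raise ValueError("duration_rule must be 'span' or 'min_side'")
        if self.depth_rule not in ("both", "either"):
            raise ValueError("depth_rule must be 'both' or 'either'")
        object.__setattr__(self, "acceptable_flags", frozenset(self.acceptable_flags))

    @classmethod
    def from_file(cls, path) -> "AlgorithmConfig":
        """Load overrides from a TOML file of key = value pairs."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "acceptable_flags" in raw:
            raw["acceptable_flags"] = frozenset(raw["acceptable_flags"])
        return cls(**raw)


def composite_times(start_year: int, n_years: int, epoch: dt.date | None = None) -> np.ndarray:
    """Day offsets of the 16-day composites of ``n_years`` calendar years.

    Composites fall on day-of-year 1, 17, ..., 353 (23 per year).  The epoch
    defaults to Jan 1 of ``start_year``.
    """
    if epoch is None:
        epoch = dt.date(start_year, 1, 1)
    out = []
    for year in range(start_year, start_year + n_years):
        offset = (dt.date(year, 1, 1) - epoch).days
        out.extend(offset + COMPOSITE_PERIOD_DAYS * k for k in range(COMPOSITES_PER_YEAR))
    return np.asarray(out, dtype=np.int64)


def composite_dates(start_year: int, n_years: int) -> list[dt.date]:
    epoch = dt.date(start_year, 1, 1)
    return [epoch + dt.timedelta(days=int(t)) for t in composite_times(start_year, n_years, epoch)]


def read_long_table(path) -> dict:
    """Read a long-format CSV (pixel_id, date, evi, flag) into EviSeries.

    Returns a mapping from pixel id to :class:`EviSeries`.  The epoch of each
    series is Jan 1 of its first observation year.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"pixel_id", "date", "evi", "flag"}
    if not required.issubset(df.columns):
        raise ValueError(f"long table must have columns {sorted(required)}")
    out = {}
    for pid, grp in df.groupby("pixel_id", sort=False):
        grp = grp.sort_values("date")
        epoch = dt.date(grp["date"].iloc[0].year, 1, 1)
        times = np.array([(d.date() - epoch).days for d in grp["date"]], dtype=np.int64)
        out[pid] = EviSeries(
            times=times,
            values=grp["evi"].to_numpy(dtype=float),
            flags=grp["flag"].to_numpy(dtype=np.int64),
            interpolated=np.zeros(len(grp), dtype=bool),
            epoch=epoch,
        )
    return out
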