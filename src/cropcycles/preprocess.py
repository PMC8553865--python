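"""Per-pixel preprocessing: QC masking, gap interpolation, windowing, alignment.

Turns a multi-year flagged EVI record into one aligned 12-month series per
year.  The steps mirror the production order of the mapping workflow:

1. ``mask_by_flags`` — observations whose reliability flag is not in the
   acceptable set become missing (NaN).
2. ``interpolate_gaps`` — missing values are filled by linear interpolation
   in time; leading/trailing gaps take the nearest valid value.
3. ``build_annual_window`` — the labeled year's 23 composites are flanked by
   six composites on each side, giving an 18-month, 35-composite window.
4. ``align_to_phenology_start`` — the window's first trough marks the start
   of the cropping season; the 23 composites from that trough form the
   12-month series handed to the polynomial fit.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .evi import (
    COMPOSITES_PER_YEAR,
    DEFAULT_ACCEPTABLE_FLAGS,
    WINDOW_FLANK,
    WINDOW_LENGTH,
    AnnualWindow,
    BoundaryYearError,
    EviSeries,
    InsufficientDataError,
)

__all__ = [
    "AlignedSeries",
    "align_to_phenology_start",
    "build_annual_window",
    "interpolate_gaps",
    "mask_by_flags",
]

#: Alignment start is searched among the first 12 composites of the window,
#: so that a full 23-composite (12-month) series always fits in 35 samples.
ALIGN_SEARCH_LENGTH = 12

#: A local minimum counts as the season trough only if it lies within this
#: EVI tolerance of the lowest smoothed value in the search range (rejects
#: shoulder minima on the flank of the previous season).
TROUGH_DEPTH_TOL = 0.02


@dataclass
class AlignedSeries:
    """A 23-composite (12-month) EVI series starting at the season trough.

    ``times`` are day offsets from the alignment start.  The bookkeeping
    fields ``n_interpolated_in_year`` and ``frac_acceptable_in_year`` refer
    to the labeled year's own 23 composites (not the shifted window) and feed
    the quality-control conditions downstream.
    """

    year: int
    times: np.ndarray
    values: np.ndarray
    n_interpolated_in_year: int
    frac_acceptable_in_year: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.times) != COMPOSITES_PER_YEAR or len(self.values) != COMPOSITES_PER_YEAR:
            raise ValueError(f"aligned series must hold {COMPOSITES_PER_YEAR} samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= self.n_interpolated_in_year <= COMPOSITES_PER_YEAR:
            raise ValueError("n_interpolated_in_year out of range")


def mask_by_flags(series: EviSeries, acceptable=DEFAULT_ACCEPTABLE_FLAGS) -> EviSeries:
    """Set observations with unacceptable reliability flags to missing (NaN).

    Times, ordering and flags are unchanged; the number of masked
    observations is ``result.n_missing``.
    """
    acceptable = frozenset(acceptable)
    bad = ~np.isin(series.flags, list(acceptable))
    values = series.values.copy()
    values[bad] = np.nan
    return series.with_values(values)


def interpolate_gaps(series: EviSeries) -> EviSeries:
    """Fill missing values by linear interpolation in time.

    Interior gaps are interpolated between the nearest valid neighbours;
    leading and trailing gaps take the nearest valid value (constant
    extension — linear extrapolation can leave the physical EVI range).
    Filled positions are marked ``interpolated``.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 observations are valid.
    """
    missing = np.isnan(series.values)
    if not missing.any():
        return series
    valid = ~missing
    if valid.sum() < 2:
        raise InsufficientDataError("need at least 2 valid observations to interpolate")
    t = series.times.astype(float)
    # np.interp clamps outside the valid support, i.e. constant extension.
    filled = series.values.copy()
    filled[missing] = np.interp(t[missing], t[valid], series.values[valid])
    return series.with_values(filled, interpolated=series.interpolated | missing)


def build_annual_window(record: EviSeries, year: int) -> AnnualWindow:
    """Extract the 18-month (35-composite) window for one calendar year.

    Raises
    ------
    BoundaryYearError
        If the record lacks the 23 in-year composites or the six flanking
        composites on either side (boundary years of the record).
    """
    dates = record.dates
    in_year = np.array([d.year == year for d in dates])
    idx = np.flatnonzero(in_year)
    if idx.size != COMPOSITES_PER_YEAR:
        raise BoundaryYearError(
            f"year {year}: expected {COMPOSITES_PER_YEAR} composites, found {idx.size}"
        )
    first, last = int(idx[0]), int(idx[-1])
    if first < WINDOW_FLANK or last + WINDOW_FLANK >= len(record):
        raise BoundaryYearError(f"year {year}: missing flanking composites for the 18-month window")
    window = record.slice(first - WINDOW_FLANK, last + WINDOW_FLANK + 1)
    return AnnualWindow(year=year, samples=window)


def _smooth3(values: np.ndarray) -> np.ndarray:
    """3-point moving average with shrinking edges; used only to locate the trough."""
    kernel = np.ones(3)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def align_to_phenology_start(
    window: AnnualWindow, acceptable=DEFAULT_ACCEPTABLE_FLAGS
) -> AlignedSeries:
    """Cut the 12-month series starting at the window's first trough.

    The start index is the first local minimum of the lightly smoothed
    window occurring within the first 12 composites (ties resolve to the
    earliest index).  If no local minimum exists there, the global minimum
    of that range is used.  The returned series holds the 23 consecutive
    composites from the start, with times rebased to the start.
    """
    values = window.samples.values
    if np.isnan(values).any():
        raise ValueError("window contains missing values; interpolate first")
    sm = _smooth3(values)
    # A candidate start is a local minimum of the smoothed curve.  The first
    # sample qualifies only together with the depth test below: a window that
    # opens on the rising limb of the previous season also has sm[0] <= sm[1],
    # but sits well above the true inter-season trough.
    floor = float(np.min(sm[:ALIGN_SEARCH_LENGTH]))
    s = None
    for i in range(ALIGN_SEARCH_LENGTH):
        left_ok = i == 0 or sm[i] <= sm[i - 1]
        right_ok = sm[i] <= sm[i + 1]
        if left_ok and right_ok and sm[i] <= floor + TROUGH_DEPTH_TOL:
            s = i
            break
    if s is None:
        s = int(np.argmin(sm[:ALIGN_SEARCH_LENGTH]))

    seg = window.samples.slice(s, s + COMPOSITES_PER_YEAR)
    core = slice(WINDOW_FLANK, WINDOW_FLANK + COMPOSITES_PER_YEAR)
    core_flags = window.samples.flags[core]
    core_interp = window.samples.interpolated[core]
    acceptable = frozenset(acceptable)
    return AlignedSeries(
        year=window.year,
        times=(seg.times - seg.times[0]).astype(float),
        values=seg.values,
        n_interpolated_in_year=int(core_interp.sum()),
        frac_acceptable_in_year=float(np.isin(core_flags, list(acceptable)).mean()),
    )
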