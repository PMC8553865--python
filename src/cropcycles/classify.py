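"""Cropping-intensity classification and the quality-control band.

Each strict maximum of the fitted phenology curve is a candidate crop cycle.
Candidates are screened by three thresholds that remove false peaks caused
by non-crop vegetation and overfitting:

* amplitude — the fitted peak EVI must exceed 0.35;
* depth — the peak must rise more than 0.01 EVI above its valleys;
* duration — the cycle must last longer than three months (90 days).

The number of surviving peaks, capped at 3, is the cropping intensity
(0 = no cropping, 1/2/3 = single/double/triple cropping).

The companion quality-control (QC) code grades each pixel-year 0-3
("best", "good", "fair", "poor") by how many of three conditions hold:
at least half the year's observations carried acceptable reliability flags;
fewer than half (<= 11 of 23) were gap-filled; and the classification is
stable when the fitted curve is perturbed by its residual standard error.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evi import AlgorithmConfig, EviSeries
from .phenofit import Extremum, PhenoFit, find_extrema, fit_poly6
from .preprocess import (
    AlignedSeries,
    align_to_phenology_start,
    build_annual_window,
    interpolate_gaps,
    mask_by_flags,
)

__all__ = [
    "IntensityResult",
    "PeakRecord",
    "assign_intensity",
    "classify_aligned",
    "classify_pixel_year",
    "filter_peaks",
    "pair_valleys",
    "qc_code",
    "qc_conditions",
]

#: Gap-filled observations allowed among the year's 23 composites
#: ("less than half of the whole EVI time series, for a total of 23 counts").
MAX_INTERPOLATED = 11


@dataclass
class PeakRecord:
    """One candidate growing-season peak with its adjacent valleys.

    Valleys are the nearest fitted minima on each side of the peak; where no
    interior minimum exists, the fitted value at the corresponding end of
    the 12-month interval serves as the valley.  Depths are peak value minus
    valley value (EVI units); durations are unsigned peak-to-valley time
    differences in days.  The pass flags are populated by
    :func:`filter_peaks` for diagnostics.
    """

    peak: Extremum
    left_valley: tuple[float, float]  # (time_days, value)
    right_valley: tuple[float, float]
    depth_left: float
    depth_right: float
    duration_left: float
    duration_right: float
    passes_amplitude: bool | None = None
    passes_depth: bool | None = None
    passes_duration: bool | None = None

    @property
    def season_span_days(self) -> float:
        """Full cycle duration: right valley time minus left valley time."""
        return self.right_valley[0] - self.left_valley[0]

    @property
    def is_valid(self) -> bool:
        return bool(self.passes_amplitude and self.passes_depth and self.passes_duration)


@dataclass(frozen=True)
class IntensityResult:
    """Final intensity and quality codes for one pixel-year."""

    intensity: int
    qc_code: int
    cond_flags: tuple[bool, bool, bool]
    n_valid_peaks: int
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError("intensity must be in 0..3")
        if self.qc_code != 3 - sum(self.cond_flags):
            raise ValueError("qc_code inconsistent with condition flags")


def pair_valleys(extrema: list[Extremum], fit: PhenoFit) -> list[PeakRecord]:
    """Pair each maximum with the nearest minimum on each side.

    Where no interior minimum flanks the peak, the fitted value at the
    corresponding interval endpoint serves as the valley.
    """
    maxima = [e for e in extrema if e.kind == "max"]
    minima = [e for e in extrema if e.kind == "min"]
    t_lo = float(fit.days_from_u(0.0))
    t_hi = float(fit.days_from_u(1.0))
    lo = (t_lo, float(fit.value_at_u(0.0)))
    hi = (t_hi, float(fit.value_at_u(1.0)))
    records = []
    for m in maxima:
        left = max(
            ((v.time_days, v.value) for v in minima if v.time_days < m.time_days),
            key=lambda tv: tv[0],
            default=lo,
        )
        right = min(
            ((v.time_days, v.value) for v in minima if v.time_days > m.time_days),
            key=lambda tv: tv[0],
            default=hi,
        )
        records.append(
            PeakRecord(
                peak=m,
                left_valley=left,
                right_valley=right,
                depth_left=m.value - left[1],
                depth_right=m.value - right[1],
                duration_left=m.time_days - left[0],
                duration_right=right[0] - m.time_days,
            )
        )
    return records


def filter_peaks(records: list[PeakRecord], config: AlgorithmConfig | None = None) -> list[PeakRecord]:
    """Apply the three-threshold peak filter; returns the valid records.

    Pass/fail flags are populated on every input record (diagnostics), and
    the records that pass all three tests are returned.
    """
    if config is None:
        config = AlgorithmConfig()
    valid = []
    for rec in records:
        rec.passes_amplitude = rec.peak.value > config.peak_min_evi
        depths = (rec.depth_left, rec.depth_right)
        depth_stat = min(depths) if config.depth_rule == "both" else max(depths)
        rec.passes_depth = depth_stat > config.min_peak_valley_depth
        if config.duration_rule == "span":
            duration_stat = rec.season_span_days
        else:
            duration_stat = min(rec.duration_left, rec.duration_right)
        rec.passes_duration = duration_stat > config.min_peak_valley_duration_days
        if rec.is_valid:
            valid.append(rec)
    return valid


def assign_intensity(valid_peaks: list, max_intensity: int = 3) -> int:
    """Cropping intensity = number of valid peaks, capped at 3."""
    return min(len(valid_peaks), max_intensity)


def _perturbed_intensity(records: list[PeakRecord], delta: float, config: AlgorithmConfig) -> int:
    """Intensity after lowering peak values and depths by the fit's delta."""
    perturbed = [
        PeakRecord(
            peak=replace(rec.peak, value=rec.peak.value - delta),
            left_valley=rec.left_valley,
            right_valley=rec.right_valley,
            depth_left=rec.depth_left - delta,
            depth_right=rec.depth_right - delta,
            duration_left=rec.duration_left,
            duration_right=rec.duration_right,
        )
        for rec in records
    ]
    return assign_intensity(filter_peaks(perturbed, config), config.max_intensity)


def qc_conditions(
    aligned: AlignedSeries,
    fit: PhenoFit,
    intensity: int,
    config: AlgorithmConfig | None = None,
) -> tuple[bool, bool, bool]:
    """The three pixel-year quality conditions.

    1. At least half the labeled year's composites carried acceptable flags.
    2. At most 11 of the year's 23 composites were gap-filled.
    3. The intensity decision is unchanged when the fitted peak values and
       peak-valley depths are lowered by the fit's residual standard error
       (delta) — i.e. the decision does not ride on the fit's noise margin.
    """
    if config is None:
        config = AlgorithmConfig()
    c1 = aligned.frac_acceptable_in_year >= 0.5
    c2 = aligned.n_interpolated_in_year <= MAX_INTERPOLATED
    records = pair_valleys(find_extrema(fit), fit)
    c3 = _perturbed_intensity(records, fit.delta, config) == intensity
    return (c1, c2, c3)


def qc_code(cond_flags: tuple[bool, bool, bool]) -> int:
    """QC code 0-3: "best" satisfies all three conditions, "good" two,
    "fair" one, "poor" none."""
    return 3 - sum(bool(f) for f in cond_flags)


def classify_aligned(aligned: AlignedSeries, config: AlgorithmConfig | None = None) -> IntensityResult:
    """Fit, peak-filter and QC-grade one aligned pixel-year series."""
    if config is None:
        config = AlgorithmConfig()
    fit = fit_poly6(aligned)
    records = pair_valleys(find_extrema(fit), fit)
    valid = filter_peaks(records, config)
    intensity = assign_intensity(valid, config.max_intensity)
    flags = qc_conditions(aligned, fit, intensity, config)
    return IntensityResult(
        intensity=intensity,
        qc_code=qc_code(flags),
        cond_flags=flags,
        n_valid_peaks=len(valid),
        delta=fit.delta,
    )


def classify_pixel_year(
    record: EviSeries, year: int, config: AlgorithmConfig | None = None
) -> IntensityResult:
    """Full per-pixel pipeline for one year: mask, fill, window, align, classify."""
    if config is None:
        config = AlgorithmConfig()
    masked = mask_by_flags(record, config.acceptable_flags)
    filled = interpolate_gaps(masked)
    window = build_annual_window(filled, year)
    aligned = align_to_phenology_start(window, config.acceptable_flags)
    return classify_aligned(aligned, config)
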