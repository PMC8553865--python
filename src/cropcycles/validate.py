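"""Map-accuracy assessment and comparison statistics.

Covers the standard toolkit for validating a categorical intensity map:
confusion matrix and overall accuracy (OA), a pooled two-proportion z-test
comparing the OA of two maps, per-pixel scatter regression, agreement
statistics on a difference map, and country-level consistency measures
against agricultural statistics — where the statistical cropping intensity
is harvested area divided by cropland area (it exceeds 1 under multiple
cropping).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .evi import DegenerateInputError
from .raster import IntensityMap

__all__ = [
    "ConfusionMatrix",
    "agreement_stats",
    "change_ratio",
    "confusion_matrix",
    "oa_ztest",
    "overall_accuracy",
    "pearson_by_region",
    "region_mean_intensity",
    "scatter_fit",
    "statistical_intensity",
    "trend_type",
]


@dataclass
class ConfusionMatrix:
    """Square cross-tabulation of reference (rows) vs predicted (columns)."""

    table: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        k = len(self.classes)
        if self.table.shape != (k, k):
            raise ValueError("table must be square over the declared classes")
        if (self.table < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.table.sum())


def confusion_matrix(reference, predicted, classes=(0, 1, 2, 3)) -> ConfusionMatrix:
    """Count cross-tabulation; cell (i, j) counts reference=i, predicted=j."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ValueError("reference and predicted must have equal length")
    if reference.size == 0:
        raise ValueError("empty input")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    table = np.zeros((k, k), dtype=np.int64)
    for ref, pred in zip(reference.ravel(), predicted.ravel()):
        try:
            table[index[int(ref)], index[int(pred)]] += 1
        except KeyError:
            raise ValueError(f"class {ref if ref not in index else pred} not in {classes}") from None
    return ConfusionMatrix(table=table, classes=classes)


def overall_accuracy(m: ConfusionMatrix) -> float:
    """OA = trace of the confusion matrix / total samples."""
    if m.n_total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(m.table)) / m.n_total


def oa_ztest(oa1: float, n1: int, oa2: float, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test comparing two overall accuracies.

    z = (oa1 - oa2) / sqrt(p*(1-p)*(1/n1 + 1/n2)) with p the pooled
    proportion; the two-sided p-value comes from the normal tail.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= oa1 <= 1 and 0 <= oa2 <= 1):
        raise ValueError("accuracies must be in [0, 1]")
    pooled = (oa1 * n1 + oa2 * n2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise DegenerateInputError("pooled proportion 0 or 1: zero variance")
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (oa1 - oa2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def scatter_fit(predicted, reference) -> tuple[float, float, float]:
    """OLS line predicted ~ reference: (slope, intercept, R^2)."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(reference) == 0:
        raise DegenerateInputError("zero-variance reference")
    res = stats.linregress(reference, predicted)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def agreement_stats(diff) -> tuple[float, float, dict]:
    """(fraction zero, mean difference, histogram over -3..3) of a
    difference grid; computed over valid (unmasked, non-NaN) pixels only."""
    arr = np.ma.masked_invalid(np.ma.asarray(diff, dtype=float))
    values = arr.compressed()
    if values.size == 0:
        raise ValueError("no valid pixels")
    hist = {k: int(np.sum(values == k)) for k in range(-3, 4)}
    return float(np.mean(values == 0)), float(values.mean()), hist


def statistical_intensity(harvested_area: float, cropland_area: float) -> float:
    """Statistical cropping intensity: harvested area / cropland area."""
    if cropland_area <= 0:
        raise ValueError("cropland area must be positive")
    return harvested_area / cropland_area


def region_mean_intensity(m: IntensityMap, region_mask: np.ndarray) -> float:
    """Unweighted mean intensity over a region's valid cropland pixels."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != m.data.shape:
        raise ValueError("region mask misaligned with the map")
    sel = region_mask & m.valid_mask
    if not sel.any():
        raise ValueError("region contains no valid pixel")
    return float(m.data[sel].mean())


def _ols_slope(series) -> float:
    y = np.asarray(series, dtype=float)
    x = np.arange(y.size, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def trend_type(gci_series, fci_series) -> int:
    """4-type country classification by the sign of each series' OLS slope.

    Type 1: both increasing; 2: map (GCI) up, statistics (FCI) down;
    3: both decreasing; 4: GCI down, FCI up.  A zero slope counts as
    increasing.
    """
    gci = np.asarray(gci_series, dtype=float)
    fci = np.asarray(fci_series, dtype=float)
    if gci.size != fci.size:
        raise ValueError("series must be aligned on years")
    if gci.size < 3:
        raise ValueError("need at least 3 years")
    g_up = _ols_slope(gci) >= 0
    f_up = _ols_slope(fci) >= 0
    return {(True, True): 1, (True, False): 2, (False, False): 3, (False, True): 4}[(g_up, f_up)]


def pearson_by_region(gci_series, fci_series, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Pearson r between map and statistical intensity series, with a
    two-sided t-test p-value and a significance flag at level alpha."""
    gci = np.asarray(gci_series, dtype=float)
    fci = np.asarray(fci_series, dtype=float)
    if gci.size != fci.size or gci.size < 3:
        raise ValueError("need >= 3 aligned years")
    if np.var(gci) == 0 or np.var(fci) == 0:
        raise DegenerateInputError("zero variance")
    r, p = stats.pearsonr(gci, fci)
    return float(r), float(p), bool(p < alpha)


def change_ratio(series) -> float:
    """Relative change over the record: (last - first) / first."""
    y = np.asarray(series, dtype=float)
    if y[0] == 0:
        raise ValueError("first value must be nonzero")
    return float((y[-1] - y[0]) / y[0])
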