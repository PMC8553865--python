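"""Sixth-order polynomial phenology fitting and analytic extrema location.

The aligned 12-month EVI series is reconstructed by a sixth-order polynomial

    EVI(t) = a0 + a1*t + a2*t^2 + ... + a6*t^6

whose degree is chosen because cropping intensity ranges over 0-3 cycles and
a degree-6 polynomial has at most 3 strict local maxima.  Growing-season
peaks are the real roots of the quintic derivative EVI'(t) = 0 with
EVI''(t) < 0; valleys have EVI''(t) > 0.

Time is normalised to u in [0, 1] before fitting, which conditions the
degree-6 Vandermonde system; an affine map carries locations back to days.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P

from .evi import COMPOSITES_PER_YEAR, FitError
from .preprocess import AlignedSeries

__all__ = ["Extremum", "PhenoFit", "find_extrema", "fit_poly6"]

DEGREE = 6
#: A derivative root counts as real if |Im| <= 1e-9 * max(1, |Re|).
REAL_ROOT_TOL = 1e-9
#: Roots closer than this (normalised time) are merged.
ROOT_MERGE_TOL = 1e-6


@dataclass
class PhenoFit:
    """A fitted sixth-order polynomial on the normalised time domain.

    Attributes
    ----------
    coeffs
        a0..a6, ascending powers of u in [0, 1].
    t0_days, span_days
        Affine map between u and days from the alignment start:
        ``days = t0_days + u * span_days``.
    delta
        Residual standard error of the fit, sqrt(RSS / (n - 7)), in EVI
        units; used downstream as a robustness margin in quality control.
    fitted
        Fitted values at the observation times (None for synthetic fits
        constructed directly from coefficients).
    """

    coeffs: np.ndarray
    t0_days: float = 0.0
    span_days: float = 1.0
    delta: float = 0.0
    fitted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.shape != (DEGREE + 1,):
            raise ValueError(f"expected {DEGREE + 1} coefficients")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.span_days == 0:
            raise ValueError("time map must be invertible (span_days != 0)")

    def u_from_days(self, days):
        return (np.asarray(days, dtype=float) - self.t0_days) / self.span_days

    def days_from_u(self, u):
        return self.t0_days + np.asarray(u, dtype=float) * self.span_days

    def value_at_u(self, u):
        return P.polyval(u, self.coeffs)

    def value_at_days(self, days):
        return self.value_at_u(self.u_from_days(days))


@dataclass(frozen=True)
class Extremum:
    """One stationary point of the fitted curve, in days from alignment start."""

    time_days: float
    value: float
    kind: str  # "max" | "min"

    def __post_init__(self) -> None:
        if self.kind not in ("max", "min"):
            raise ValueError("kind must be 'max' or 'min'")


def fit_poly6(series: AlignedSeries) -> PhenoFit:
    """Least-squares degree-6 fit of an aligned series.

    Raises
    ------
    FitError
        If the design is rank-deficient (fewer than 8 distinct times).
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.values, dtype=float)
    if len(t) != COMPOSITES_PER_YEAR:
        raise FitError(f"expected {COMPOSITES_PER_YEAR} samples")
    if np.unique(t).size < DEGREE + 2:
        raise FitError("need at least 8 distinct observation times")
    t0, span = t[0], t[-1] - t[0]
    u = (t - t0) / span
    design = np.vander(u, DEGREE + 1, increasing=True)
    coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < DEGREE + 1:
        raise FitError("rank-deficient design matrix")
    fitted = design @ coeffs
    rss = float(np.sum((y - fitted) ** 2))
    delta = float(np.sqrt(rss / (len(y) - (DEGREE + 1))))
    return PhenoFit(coeffs=coeffs, t0_days=float(t0), span_days=float(span), delta=delta, fitted=fitted)


def find_extrema(fit: PhenoFit) -> list[Extremum]:
    """Interior extrema of the fitted polynomial, sorted by time.

    Real roots of the quintic derivative are located by the companion-matrix
    eigenvalue method, restricted to the open interval (0, 1) of normalised
    time — roots at the exact endpoints are truncation artefacts, not
    seasons.  Each root is classified by the sign of the second derivative;
    a vanishing second derivative (saddle) is not counted.  A degree-6
    polynomial can have at most 3 maxima.
    """
    d1 = P.polyder(fit.coeffs)
    d2 = P.polyder(d1)
    if not np.any(d1 != 0):
        return []
    roots = P.polyroots(d1)
    real = roots[np.abs(roots.imag) <= REAL_ROOT_TOL * np.maximum(1.0, np.abs(roots.real))].real
    real = np.sort(real[(real > REAL_ROOT_TOL) & (real < 1.0 - REAL_ROOT_TOL)])
    merged: list[float] = []
    for r in real:
        if merged and r - merged[-1] <= ROOT_MERGE_TOL:
            continue
        merged.append(float(r))
    out = []
    for u in merged:
        curv = float(P.polyval(u, d2))
        if curv == 0.0:
            continue
        out.append(
            Extremum(
                time_days=float(fit.days_from_u(u)),
                value=float(fit.value_at_u(u)),
                kind="max" if curv < 0 else "min",
            )
        )
    return out
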