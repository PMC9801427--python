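"""Hydration-series assembly, regime classification, and dome detection.

Observables measured across a hydration series (wt % water on the
x-axis) exhibit a re-entrant, dome-shaped response when the protein
first unfolds at low hydration and then recovers toward its native
state as water is added.  The dome test compares the best monotone fit
(either direction, pool-adjacent-violators) against the best unimodal
up-then-down fit; a sufficiently large relative improvement in the sum
of squared errors flags a dome.  The unimodal family contains both
monotone families as edge cases, so its SSE can never exceed theirs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import linregress
from sklearn.isotonic import IsotonicRegression

from .exceptions import InsufficientDataError, InvalidInputError
from .sans import ConformationalState

#: Regime boundaries in wt % water (low < lo <= intermediate <= hi < high).
REGIME_BOUNDS = (10.0, 40.0)

#: Relative SSE improvement of the unimodal fit over the best monotone fit
#: required to call a dome.
DOME_IMPROVEMENT = 0.2


@dataclass
class HydrationSeries:
    wt_percent: np.ndarray
    values: np.ndarray
    uncertainties: Optional[np.ndarray] = None
    labels: Optional[list[str]] = None
    observable_name: str = ""

    def __post_init__(self) -> None:
        self.wt_percent = np.asarray(self.wt_percent, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wt_percent.shape != self.values.shape or self.wt_percent.ndim != 1:
            raise InvalidInputError("wt_percent and values must be 1-D arrays of equal length")
        if self.wt_percent.size < 3:
            raise InvalidInputError("a hydration series needs >= 3 points")
        if np.any((self.wt_percent < 0) | (self.wt_percent > 100)):
            raise InvalidInputError("wt % values must lie in [0, 100]")
        if np.unique(self.wt_percent).size != self.wt_percent.size:
            raise InvalidInputError("wt % values must be unique")
        order = np.argsort(self.wt_percent)
        self.wt_percent = self.wt_percent[order]
        self.values = self.values[order]
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)[order]
        if self.labels is not None:
            self.labels = [self.labels[i] for i in order]

    def __len__(self) -> int:
        return self.wt_percent.size


def classify_regime(wt: float, bounds: tuple[float, float] = REGIME_BOUNDS) -> str:
    """'low' (< bounds[0]), 'intermediate' (inclusive), or 'high' (> bounds[1])."""
    if not 0 <= wt <= 100:
        raise InvalidInputError(f"wt % must be in [0, 100], got {wt}")
    lo, hi = bounds
    if wt < lo:
        return "low"
    if wt <= hi:
        return "intermediate"
    return "high"


@dataclass(frozen=True)
class DomeResult:
    is_dome: bool
    peak_location: float  # wt % at the unimodal fit's maximum
    monotone_sse: float  # best of the two monotone directions
    unimodal_sse: float
    improvement: float  # relative SSE improvement of unimodal over monotone
    unimodal_fit: np.ndarray = field(compare=False, default=None)


def _isotonic(x: np.ndarray, y: np.ndarray, increasing: bool) -> np.ndarray:
    if y.size == 0:
        return y
    if y.size == 1:
        return y.copy()
    return IsotonicRegression(increasing=increasing).fit_transform(x, y)


def dome_test(s: HydrationSeries, improvement_threshold: float = DOME_IMPROVEMENT) -> DomeResult:
    """Nested monotone-vs-unimodal regression test for a dome response.

    The unimodal fit is the best over all peak splits k of (isotonic
    increasing on points 0..k) + (isotonic decreasing on points k+1..end),
    including the degenerate splits that reduce to pure monotone fits.
    """
    if len(s) < 4:
        raise InsufficientDataError("dome test needs >= 4 points")
    x, y = s.wt_percent, s.values

    inc = _isotonic(x, y, True)
    dec = _isotonic(x, y, False)
    sse_inc = float(np.sum((inc - y) ** 2))
    sse_dec = float(np.sum((dec - y) ** 2))
    monotone_sse = min(sse_inc, sse_dec)

    best_sse, best_fit = np.inf, None
    for k in range(-1, len(s)):
        left = _isotonic(x[: k + 1], y[: k + 1], True)
        right = _isotonic(x[k + 1 :], y[k + 1 :], False)
        fit = np.concatenate([left, right])
        sse = float(np.sum((fit - y) ** 2))
        if sse < best_sse:
            best_sse, best_fit = sse, fit
    unimodal_sse = min(best_sse, monotone_sse)

    improvement = 0.0 if monotone_sse == 0 else (monotone_sse - unimodal_sse) / monotone_sse
    peak = float(x[int(np.argmax(best_fit))])
    return DomeResult(
        is_dome=improvement >= improvement_threshold,
        peak_location=peak,
        monotone_sse=monotone_sse,
        unimodal_sse=unimodal_sse,
        improvement=improvement,
        unimodal_fit=best_fit,
    )


@dataclass(frozen=True)
class ParametricFit:
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    excluded: tuple[str, ...]


def parametric_fit(states: Sequence[ConformationalState],
                   exclude_labels: Iterable[str] = ()) -> ParametricFit:
    """OLS of monomer compactness r_1 on aggregation number N_agg.

    Samples whose labels are in ``exclude_labels`` are dropped before
    fitting — conformational states that sit off the hydrated-series
    correlation (such as the anhydrous solvent) can thus be excluded
    explicitly rather than silently down-weighted.
    """
    excluded = tuple(exclude_labels)
    kept = [st for st in states if st.label not in excluded]
    if len(kept) < 3:
        raise InsufficientDataError(f"parametric fit needs >= 3 states, got {len(kept)}")
    x = np.array([st.n_agg for st in kept])
    y = np.array([st.r1 for st in kept])
    if np.ptp(x) == 0:
        raise InvalidInputError("aggregation numbers are degenerate (zero variance)")
    res = linregress(x, y)
    return ParametricFit(float(res.slope), float(res.intercept),
                         float(res.rvalue**2), len(kept), excluded)
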