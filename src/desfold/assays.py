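"""Turbidimetric lysozyme activity analysis.

Lysozyme activity is followed as the clearing of a Micrococcus
cell-wall suspension: the absorbance at 450 nm decays as cells lyse.
The initial lysis rate gives the enzymatic activity; dividing by the
enzyme mass in the assay yields the specific activity in international
units (1 IU = 0.001 dA450/min by the standard turbidimetric
definition), and normalizing against the aqueous-buffer reference gives
the relative activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import InsufficientDataError, InvalidInputError, UndefinedResultError

#: 1 international unit = 0.001 absorbance decrease per minute.
IU_FACTOR = 0.001

#: Fraction of A(0) that bounds the default initial-rate window.
DECAY_WINDOW_FRAC = 0.10

MIN_WINDOW_POINTS = 4


@dataclass
class LysisCurve:
    time: np.ndarray  # min, strictly increasing from 0
    a450: np.ndarray  # absorbance
    enzyme_mass: float = 1.0  # mg in the assay
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.a450 = np.asarray(self.a450, dtype=float)
        if self.time.shape != self.a450.shape or self.time.ndim != 1:
            raise InvalidInputError("time and a450 must be 1-D arrays of equal length")
        if self.time.size < 5:
            raise InvalidInputError("a lysis curve needs >= 5 points")
        if self.time[0] != 0 or not np.all(np.diff(self.time) > 0):
            raise InvalidInputError("time must start at 0 and increase strictly")
        if not np.all(np.isfinite(self.a450)):
            raise InvalidInputError("absorbances must be finite")
        if self.enzyme_mass <= 0:
            raise InvalidInputError("enzyme mass must be positive")


@dataclass(frozen=True)
class InitialRate:
    rate: float  # AU/min, positive for decaying curves
    n_points: int
    no_lysis: bool  # True when no decay was detected


def initial_rate(c: LysisCurve, window: Optional[tuple[float, float]] = None) -> InitialRate:
    """Initial lysis rate: minus the OLS slope over the initial window.

    The default window runs from t = 0 until the total decay first
    reaches 10% of A(0) (at least 4 points); an explicit ``(t0, t1)``
    window overrides the rule.
    """
    t, a = c.time, c.a450
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
    else:
        decay = a[0] - a
        threshold = DECAY_WINDOW_FRAC * a[0]
        beyond = np.where(decay >= threshold)[0]
        cutoff = beyond[0] if beyond.size else t.size - 1
        mask = np.arange(t.size) <= max(cutoff, MIN_WINDOW_POINTS - 1)
    if mask.sum() < MIN_WINDOW_POINTS:
        raise InsufficientDataError(
            f"initial-rate window holds {int(mask.sum())} points; need >= {MIN_WINDOW_POINTS}"
        )
    slope = np.polyfit(t[mask], a[mask], 1)[0]
    rate = -float(slope)
    no_lysis = rate <= 0 or (a[0] - a[-1]) <= 0
    return InitialRate(max(rate, 0.0) if no_lysis else rate, int(mask.sum()), no_lysis)


def specific_activity(c: LysisCurve, window: Optional[tuple[float, float]] = None,
                      iu_factor: float = IU_FACTOR) -> float:
    """Specific activity in IU per mg of enzyme."""
    r = initial_rate(c, window)
    return r.rate / (iu_factor * c.enzyme_mass)


def relative_activity(sample: LysisCurve, reference: LysisCurve,
                      window: Optional[tuple[float, float]] = None,
                      iu_factor: float = IU_FACTOR) -> float:
    """Specific activity of the sample normalized to the reference
    (typically the enzyme in aqueous buffer)."""
    ref = specific_activity(reference, window, iu_factor)
    if ref == 0:
        raise UndefinedResultError("reference curve shows no lysis; relative activity undefined")
    return specific_activity(sample, window, iu_factor) / ref
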