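"""Generic wavelength-indexed spectrum container.

One container serves absorbance, raw/mean-residue ellipticity and
fluorescence emission; the ``kind`` tag lets each analysis stage enforce
that it received the signal it expects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import InvalidInputError

#: Allowed spectrum kinds.
KINDS = ("absorbance", "ellipticity", "mre", "emission")

#: Relative tolerance on grid spacing used by :meth:`Spectrum.is_uniform`.
GRID_TOL_NM = 1e-6


@dataclass
class Spectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray
    uncertainties: Optional[np.ndarray] = None
    kind: str = "absorbance"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise InvalidInputError(f"unknown spectrum kind {self.kind!r}; expected one of {KINDS}")
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.values.shape:
            raise InvalidInputError("wavelengths and values must be 1-D arrays of equal length")
        if self.wavelengths.size < 2:
            raise InvalidInputError("a spectrum needs at least two samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("spectrum values must be finite")
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if self.uncertainties.shape != self.values.shape:
                raise InvalidInputError("uncertainties must match values in length")
            if not np.all(self.uncertainties > 0):
                raise InvalidInputError("uncertainties must be positive")

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def spacing(self) -> float:
        """Median grid spacing, nm."""
        return float(np.median(np.diff(self.wavelengths)))

    def is_uniform(self, tol: float = GRID_TOL_NM) -> bool:
        d = np.diff(self.wavelengths)
        return bool(np.all(np.abs(d - d[0]) <= tol))

    def crop(self, window: tuple[float, float]) -> "Spectrum":
        """Sub-spectrum on the closed wavelength window [lo, hi]."""
        lo, hi = window
        if lo >= hi:
            raise InvalidInputError(f"window lower bound must be < upper, got {window}")
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if mask.sum() < 2:
            raise InvalidInputError(f"window {window} contains fewer than 2 samples")
        unc = self.uncertainties[mask] if self.uncertainties is not None else None
        return replace(self, wavelengths=self.wavelengths[mask], values=self.values[mask],
                       uncertainties=unc, metadata=dict(self.metadata))

    def covers(self, window: tuple[float, float]) -> bool:
        return self.wavelengths[0] <= window[0] and self.wavelengths[-1] >= window[1]
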