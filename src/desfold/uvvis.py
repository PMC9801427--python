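"""Second-derivative UV-vis and tryptophan-emission analysis.

The near-UV absorbance band of a protein (~280 nm) overlaps the
tyrosine (~287 nm) and tryptophan (~295 nm) contributions; the second
derivative d2Abs/dlambda2 resolves them.  Two scalar probes of the
aromatic-residue environment are extracted: the Tyr feature position
(a bathochromic shift reports a more polar milieu) and the ratio of the
Tyr and Trp second-derivative amplitudes.  For intrinsic fluorescence,
the center of spectral mass (CSM) of the Trp emission band condenses
position and intensity distribution into a single wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import (
    FeatureNotFoundError,
    InvalidInputError,
    NonUniformGridError,
    UndefinedResultError,
)
from .spectrum import Spectrum

TYR_WINDOW = (283.0, 291.0)
TRP_WINDOW = (291.0, 299.0)
CSM_WINDOW = (305.0, 380.0)


@dataclass(frozen=True)
class ChromophoreParameters:
    """Aromatic-environment descriptors from a second-derivative spectrum.

    Amplitudes are positive magnitudes; with ``mode="peak_to_trough"``
    each is the vertical distance from the window's most negative local
    minimum to its outward-side satellite maximum (short-wavelength side
    for the Tyr feature, long-wavelength side for Trp), with
    ``mode="extremum"`` the absolute value of the minimum itself.
    """

    lambda_tyr: float  # nm
    amp_tyr: float
    amp_trp: float
    ratio: float  # amp_tyr / amp_trp
    mode: str = "peak_to_trough"


@dataclass(frozen=True)
class TrpEmissionSummary:
    csm: float  # nm
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise InvalidInputError("window lower bound must be < upper")
        if not lo <= self.csm <= hi:
            raise InvalidInputError("CSM outside its analysis window")


def second_derivative(s: Spectrum, window_points: int = 9, poly_order: int = 3) -> Spectrum:
    """Savitzky-Golay second derivative on the spectrum's own grid.

    The half-window at each end is extrapolated by the filter's edge
    polynomials and flagged via ``metadata["edge_points"]``; feature
    extraction should stay in the interior.
    """
    if s.kind != "absorbance":
        raise InvalidInputError(f"second derivative is defined for absorbance spectra, got kind={s.kind!r}")
    if not s.is_uniform():
        raise NonUniformGridError(
            "wavelength grid is not uniform; resample onto a uniform grid before differentiating"
        )
    if window_points % 2 != 1:
        raise InvalidInputError("window_points must be odd")
    if window_points < poly_order + 2:
        raise InvalidInputError("window_points must be >= poly_order + 2")
    if window_points > len(s):
        raise InvalidInputError(f"window of {window_points} points exceeds spectrum length {len(s)}")
    d2 = savgol_filter(s.values, window_points, poly_order, deriv=2, delta=s.spacing)
    meta = dict(s.metadata)
    meta.update(derivative_order=2, edge_points=window_points // 2,
                savgol=dict(window_points=window_points, poly_order=poly_order))
    return replace(s, values=d2, uncertainties=None, metadata=meta)


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of strict interior local minima."""
    v = values
    return np.where((v[1:-1] < v[:-2]) & (v[1:-1] < v[2:]))[0] + 1


def _local_maxima(values: np.ndarray) -> np.ndarray:
    v = values
    return np.where((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:]))[0] + 1


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabolic interpolation of an extremum at index i."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(x[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    h = x[i + 1] - x[i]
    return float(x[i] + delta * h), float(y1 - 0.25 * (y0 - y2) * delta)


def _window_minimum(d2: Spectrum, window: tuple[float, float], name: str) -> tuple[int, float, float]:
    """Most negative local minimum inside a window; returns (index, lambda, value)."""
    wl, v = d2.wavelengths, d2.values
    in_win = (wl >= window[0]) & (wl <= window[1])
    minima = [i for i in _local_minima(v) if in_win[i]]
    if not minima:
        raise FeatureNotFoundError(f"no local minimum in the {name} window {window}")
    i = min(minima, key=lambda j: v[j])
    lam, val = _parabolic_refine(wl, v, i)
    return i, lam, val


def _satellite_maximum(d2: Spectrum, i_min: int, side: str) -> float:
    """Value of the nearest local maximum on the requested side of a minimum.

    The amplitude of each chromophore feature is measured to its own
    outward-side satellite (blue side for Tyr, red side for Trp): the
    satellite on the far side from the partner band is unpolluted by the
    inter-band saddle, which keeps equal bands exactly symmetric and the
    amplitude linear in its band's height.  Falls back to the nearest
    maximum on the other side if the requested side has none.
    """
    maxima = _local_maxima(d2.values)
    if maxima.size == 0:
        return float(np.max(d2.values))
    on_side = maxima[maxima < i_min] if side == "blue" else maxima[maxima > i_min]
    if on_side.size == 0:
        on_side = maxima
    i = int(on_side[np.argmin(np.abs(on_side - i_min))])
    _, val = _parabolic_refine(d2.wavelengths, d2.values, i)
    return val


def tyr_trp_parameters(
    d2: Spectrum,
    tyr_window: tuple[float, float] = TYR_WINDOW,
    trp_window: tuple[float, float] = TRP_WINDOW,
    mode: str = "peak_to_trough",
) -> ChromophoreParameters:
    """Locate the Tyr and Trp second-derivative features and their amplitude ratio."""
    if mode not in ("peak_to_trough", "extremum"):
        raise InvalidInputError(f"unknown amplitude mode {mode!r}")
    if not (d2.covers(tyr_window) and d2.covers(trp_window)):
        raise InvalidInputError("second-derivative spectrum does not cover both search windows")

    i_tyr, lam_tyr, v_tyr = _window_minimum(d2, tyr_window, "Tyr")
    i_trp, _, v_trp = _window_minimum(d2, trp_window, "Trp")

    if mode == "extremum":
        amp_tyr, amp_trp = abs(v_tyr), abs(v_trp)
    else:
        amp_tyr = _satellite_maximum(d2, i_tyr, "blue") - v_tyr
        amp_trp = _satellite_maximum(d2, i_trp, "red") - v_trp
    if amp_trp == 0:
        raise FeatureNotFoundError("Trp amplitude is zero; ratio undefined")
    return ChromophoreParameters(lam_tyr, amp_tyr, amp_trp, amp_tyr / amp_trp, mode)


def center_of_spectral_mass(s: Spectrum, window: tuple[float, float] = CSM_WINDOW) -> TrpEmissionSummary:
    """Intensity-weighted mean emission wavelength over the closed window.

    CSM = sum(lambda * I) / sum(I), computed in the wavelength domain
    (no wavenumber conversion).
    """
    if s.kind != "emission":
        raise InvalidInputError(f"CSM is defined for emission spectra, got kind={s.kind!r}")
    if not s.covers(window):
        raise InvalidInputError(f"spectrum does not cover the CSM window {window}")
    sub = s.crop(window)
    total = sub.values.sum()
    if total == 0:
        raise UndefinedResultError("all-zero intensity in the CSM window")
    csm = float((sub.wavelengths * sub.values).sum() / total)
    return TrpEmissionSummary(csm=csm, window=window)
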