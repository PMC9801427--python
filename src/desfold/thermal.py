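"""Two-state thermal-unfolding thermodynamics from melting curves.

A melting curve (ellipticity at 222 nm vs temperature) is modelled as a
two-state native/denatured equilibrium with sloped linear baselines:

    y(T) = [y_N(T) + y_D(T) * K(T)] / (1 + K(T)),
    K(T) = exp[-(dH_m / R) * (1/T - 1/T_m)]        (van't Hoff)

with y_N = a_N + b_N*T, y_D = a_D + b_D*T.  The fit yields the melting
temperature T_m (fraction denatured 1/2), the van't Hoff enthalpy dH_m,
and the free energy of denaturation at any reference temperature,
dG_D(T) = dH_m * (1 - T/T_m) for dCp = 0 (the full Gibbs-Helmholtz form
is available via a heat-capacity increment).  Positive dG_D means the
native state is favored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks, savgol_filter

from .exceptions import (
    DegenerateBaselineError,
    FitFailureError,
    InvalidInputError,
    InsufficientDataError,
)
from .units import R_GAS, celsius_to_kelvin


@dataclass
class MeltingCurve:
    temperatures: np.ndarray  # K, strictly increasing
    signal: np.ndarray  # ellipticity at 222 nm (mdeg or MRE)
    uncertainties: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.shape != self.signal.shape or self.temperatures.ndim != 1:
            raise InvalidInputError("temperatures and signal must be 1-D arrays of equal length")
        if self.temperatures.size < 10:
            raise InvalidInputError("a melting curve needs >= 10 points spanning both baselines")
        if not np.all(np.isfinite(self.temperatures)) or not np.all(np.diff(self.temperatures) > 0):
            raise InvalidInputError("temperatures must be finite and strictly increasing")
        if self.uncertainties is not None:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if self.uncertainties.shape != self.signal.shape or not np.all(self.uncertainties > 0):
                raise InvalidInputError("uncertainties must be positive and match signal length")

    @classmethod
    def from_celsius(cls, t_celsius, signal, **kw) -> "MeltingCurve":
        return cls(celsius_to_kelvin(np.asarray(t_celsius, dtype=float)), signal, **kw)

    def __len__(self) -> int:
        return self.temperatures.size


@dataclass
class TwoStateFit:
    tm: float  # K
    dh_m: float  # kJ/mol, van't Hoff enthalpy at T_m
    a_n: float
    b_n: float
    a_d: float
    b_d: float
    dcp: float = 0.0  # kJ/mol/K, optional heat-capacity increment
    fd_curve: Optional[np.ndarray] = None  # fraction denatured at the input temperatures
    converged: bool = True
    tm_in_span: bool = True
    multi_state_flag: bool = False  # True: data show >1 transition, two-state is an approximation
    covariance: Optional[np.ndarray] = None  # parameter order (tm, dh_m, a_n, b_n, a_d, b_d)
    residual_rms: float = float("nan")
    label: str = ""
    diagnostics: dict = field(default_factory=dict)

    def native_baseline(self, t: np.ndarray) -> np.ndarray:
        return self.a_n + self.b_n * np.asarray(t, dtype=float)

    def denatured_baseline(self, t: np.ndarray) -> np.ndarray:
        return self.a_d + self.b_d * np.asarray(t, dtype=float)

    def equilibrium_constant(self, t: np.ndarray) -> np.ndarray:
        return np.exp(-(self.dh_m / R_GAS) * (1.0 / np.asarray(t, dtype=float) - 1.0 / self.tm))

    def model_fd(self, t: np.ndarray) -> np.ndarray:
        k = self.equilibrium_constant(t)
        return k / (1.0 + k)

    def model_signal(self, t: np.ndarray) -> np.ndarray:
        fd = self.model_fd(t)
        return self.native_baseline(t) * (1 - fd) + self.denatured_baseline(t) * fd


def two_state_signal(t, tm, dh_m, a_n, b_n, a_d, b_d):
    """Two-state melting signal (module-level for generators and fitting)."""
    t = np.asarray(t, dtype=float)
    k = np.exp(-(dh_m / R_GAS) * (1.0 / t - 1.0 / tm))
    fd = k / (1.0 + k)
    return (a_n + b_n * t) * (1 - fd) + (a_d + b_d * t) * fd


@dataclass
class FractionDenatured:
    values: np.ndarray  # clipped to [0, 1]
    n_clipped: int  # diagnostic: points clipped into range


def fraction_denatured(m: MeltingCurve, fit: TwoStateFit) -> FractionDenatured:
    """f_D(T) = (y_N - y) / (y_N - y_D) with the fit's linear baselines."""
    t = m.temperatures
    y_n = fit.native_baseline(t)
    y_d = fit.denatured_baseline(t)
    denom = y_n - y_d
    if np.any(denom == 0) or np.any(np.sign(denom) != np.sign(denom[0])):
        raise DegenerateBaselineError("native and denatured baselines cross inside the data span")
    fd = (y_n - m.signal) / denom
    clipped = int(np.sum((fd < 0) | (fd > 1)))
    return FractionDenatured(np.clip(fd, 0.0, 1.0), clipped)


def transition_count(fd: np.ndarray, temperatures: np.ndarray, prominence_frac: float = 0.1) -> int:
    """Number of unfolding transitions: peaks of the smoothed df_D/dT.

    A peak counts when its prominence reaches ``prominence_frac`` of the
    derivative's global maximum.
    """
    fd = np.asarray(fd, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    if fd.size < 5:
        raise InsufficientDataError("need >= 5 points to count transitions")
    if np.ptp(fd) < 1e-2:  # essentially flat: no transition
        return 0
    window = min(7, fd.size if fd.size % 2 == 1 else fd.size - 1)
    smoothed = savgol_filter(fd, window, 2) if window >= 4 else fd
    deriv = np.gradient(smoothed, t)
    top = deriv.max()
    if top <= 0:
        return 0
    peaks, _ = find_peaks(deriv, prominence=prominence_frac * top)
    if peaks.size == 0:
        # a transition truncated at either end puts its derivative maximum
        # on the boundary, where find_peaks is blind
        return 1 if (fd[-1] - fd[0]) > 0.1 else 0
    return int(peaks.size)


def _initial_guess(m: MeltingCurve) -> tuple[float, float, float, float, float, float]:
    """Heuristic start: T_m at max |dy/dT|, baselines from the outer 20%."""
    t, y = m.temperatures, m.signal
    n = len(m)
    window = min(7, n if n % 2 == 1 else n - 1)
    y_s = savgol_filter(y, window, 2) if window >= 4 else y
    dy = np.gradient(y_s, t)
    tm0 = float(t[np.argmax(np.abs(dy))])

    k = max(3, int(round(0.2 * n)))
    b_n, a_n = np.polyfit(t[:k], y[:k], 1)
    b_d, a_d = np.polyfit(t[-k:], y[-k:], 1)

    y_nn = a_n + b_n * t
    y_dd = a_d + b_d * t
    denom = y_nn - y_dd
    with np.errstate(divide="ignore", invalid="ignore"):
        fd0 = np.clip(np.where(denom != 0, (y_nn - y) / denom, 0.5), 0.0, 1.0)
    dfd = np.gradient(savgol_filter(fd0, window, 2) if window >= 4 else fd0, t)
    slope_tm = float(np.interp(tm0, t, dfd))
    dh0 = max(50.0, 4.0 * R_GAS * tm0**2 * slope_tm)
    return tm0, dh0, float(a_n), float(b_n), float(a_d), float(b_d)


def fit_two_state(
    m: MeltingCurve,
    *,
    initial: Optional[tuple] = None,
    prominence_frac: float = 0.1,
) -> TwoStateFit:
    """Nonlinear least-squares fit of the six-parameter two-state model.

    Residuals are weighted by the point uncertainties when present.  If
    the data show more than one transition the fit still runs but is
    flagged ``multi_state_flag`` (approximated as a two-state transition).
    """
    t, y = m.temperatures, m.signal
    sigma = m.uncertainties if m.uncertainties is not None else np.ones_like(y)
    p0 = np.array(initial if initial is not None else _initial_guess(m), dtype=float)

    def resid(p):
        return (two_state_signal(t, *p) - y) / sigma

    lo = [t[0] - 50.0, 1e-3, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [t[-1] + 50.0, 5e4, np.inf, np.inf, np.inf, np.inf]
    p0 = np.clip(p0, lo, hi)
    sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not sol.success:
        raise FitFailureError("two-state fit did not converge", {"status": sol.status, "message": sol.message})

    tm, dh_m, a_n, b_n, a_d, b_d = sol.x
    if dh_m <= 0:
        raise FitFailureError("fitted van't Hoff enthalpy is non-positive", {"dh_m": dh_m})

    # covariance from the Jacobian (Gauss-Newton approximation)
    cov = None
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(1, len(t) - 6)
        s2 = 2.0 * sol.cost / dof
        cov = s2 * np.linalg.pinv(jtj)
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        pass

    fit = TwoStateFit(
        tm=float(tm), dh_m=float(dh_m), a_n=float(a_n), b_n=float(b_n),
        a_d=float(a_d), b_d=float(b_d),
        converged=bool(sol.success),
        tm_in_span=bool(t[0] <= tm <= t[-1]),
        covariance=cov,
        residual_rms=float(np.sqrt(np.mean((two_state_signal(t, *sol.x) - y) ** 2))),
        label=m.label,
        diagnostics={"cost": float(sol.cost), "nfev": int(sol.nfev)},
    )
    try:
        fit.fd_curve = fraction_denatured(m, fit).values
    except DegenerateBaselineError:
        # baselines crossing usually means the data are not two-state;
        # fall back to the model-evaluated fraction and flag the fit
        fit.fd_curve = fit.model_fd(t)
        fit.diagnostics["degenerate_baselines"] = True
        fit.multi_state_flag = True
        return fit
    fit.multi_state_flag = bool(transition_count(fit.fd_curve, t, prominence_frac) > 1)
    return fit


def delta_g_at(fit: TwoStateFit, t_ref: float) -> float:
    """Free energy of denaturation at ``t_ref`` (K), kJ/mol.

    dG_D(T) = dH_m (1 - T/T_m) - dCp [(T_m - T) + T ln(T/T_m)];
    the heat-capacity term vanishes for the default dCp = 0.  Positive
    values indicate a stabilized native state; dG_D(T_m) = 0 exactly.
    """
    if t_ref <= 0:
        raise InvalidInputError("reference temperature must be positive kelvin")
    dg = fit.dh_m * (1.0 - t_ref / fit.tm)
    if fit.dcp:
        dg -= fit.dcp * ((fit.tm - t_ref) + t_ref * np.log(t_ref / fit.tm))
    return float(dg)
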