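"""Small-angle scattering analysis: Guinier fit, normalized Kratky
transform, regularized indirect Fourier transform (IFT), and
conformational parameter extraction.

The pair-distance distribution function p(r) is the histogram of
distances between pairs of points inside the scatterer; it is related to
the scattering curve by

    I(q) = 4 pi  \\int_0^Dmax  p(r) sin(qr)/(qr) dr .

The inversion expands p(r) on linear spline (hat) nodes with
p(0) = p(Dmax) = 0, and minimizes

    chi^2 + alpha * || second difference of node values ||^2

subject to p >= 0, solved as nonnegative least squares on the stacked
augmented system — a smoothness-regularized inversion in the indirect
Fourier transform tradition.  Derived parameters: the maximum dimension
D_max, the forward scattering I(0) = 4 pi \\int p dr, the radius of
gyration R_g^2 = \\int r^2 p dr / (2 \\int p dr), and the position r_1 of
the first interior maximum of p(r) — a proxy for monomer compactness.
Self-association is quantified by the aggregation number N_agg, the
apparent weight-average mass ratio from concentration-normalized I(0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import nnls

from .exceptions import (
    FeatureNotFoundError,
    InsufficientDataError,
    InvalidInputError,
)

N_NODES_DEFAULT = 101
GAUSS_POINTS_PER_ELEMENT = 4
QRG_LIMIT_DEFAULT = 1.3


@dataclass
class SASProfile:
    q: np.ndarray  # A^-1, strictly increasing, > 0
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    concentration: Optional[float] = None  # mg/mL, needed for N_agg
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.intensity.shape:
            raise InvalidInputError("q and intensity must be 1-D arrays of equal length")
        if not np.all(self.q > 0) or not np.all(np.diff(self.q) > 0):
            raise InvalidInputError("q must be positive and strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidInputError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape or not np.all(self.sigma > 0):
                raise InvalidInputError("sigma must be positive and match q in length")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class PairDistanceDistribution:
    r: np.ndarray  # A, 0 .. d_max inclusive
    p: np.ndarray
    d_max: float
    i0: float
    rg: float
    r1: Optional[float]  # first interior maximum; None when p == 0
    sigma_p: Optional[np.ndarray] = None
    regularization_alpha: float = 0.0
    fit_chi2: float = float("nan")  # reduced chi^2 of the re-projected model

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.shape != self.p.shape:
            raise InvalidInputError("r and p must have equal length")
        scale = np.max(np.abs(self.p)) if self.p.size else 0.0
        tol = 1e-9 * max(scale, 1.0)
        if abs(self.p[0]) > tol or abs(self.p[-1]) > tol:
            raise InvalidInputError("p(0) and p(d_max) must vanish")
        if np.any(self.p < -tol):
            raise InvalidInputError("p(r) must be nonnegative")
        if scale > 0:
            rg_check = _rg_from_pr(self.r, self.p)
            if abs(rg_check - self.rg) > 1e-6 * max(abs(self.rg), 1e-12):
                raise InvalidInputError("stored rg inconsistent with second moment of p(r)")


@dataclass(frozen=True)
class ConformationalState:
    """Per-sample structural summary used in parametric hydration plots."""

    d_max: float
    r1: float
    n_agg: float
    rg: float
    i0_per_conc: Optional[float] = None
    label: str = ""


def _rg_from_pr(r: np.ndarray, p: np.ndarray) -> float:
    norm = np.trapezoid(p, r)
    if norm <= 0:
        return 0.0
    return float(np.sqrt(np.trapezoid(r**2 * p, r) / (2.0 * norm)))


# ---------------------------------------------------------------------------
# Guinier and Kratky
# ---------------------------------------------------------------------------

def guinier_fit(profile: SASProfile, qrg_limit: float = QRG_LIMIT_DEFAULT,
                min_points: int = 5, max_iter: int = 20) -> tuple[float, float]:
    """Iteratively self-consistent Guinier fit; returns (rg, i0).

    Fits ln I = ln I0 - (rg^2/3) q^2 on the window q*rg <= qrg_limit,
    re-deriving the window from each rg estimate until it stabilizes.
    """
    pos = profile.intensity > 0
    q, i = profile.q[pos], profile.intensity[pos]
    if q.size < min_points:
        raise InsufficientDataError("not enough positive-intensity points for a Guinier fit")
    w = None
    if profile.sigma is not None:
        w = (profile.sigma[pos] / i)  # sigma of ln I

    mask = np.zeros_like(q, dtype=bool)
    mask[: max(min_points, q.size // 3)] = True
    rg_prev = np.inf
    rg = i0 = 0.0
    for _ in range(max_iter):
        qq, yy = q[mask] ** 2, np.log(i[mask])
        weights = 1.0 / w[mask] ** 2 if w is not None else None
        slope, intercept = np.polyfit(qq, yy, 1, w=np.sqrt(weights) if weights is not None else None)
        if slope >= 0:
            raise InsufficientDataError("Guinier fit produced a non-negative slope (no decay at low q)")
        rg = float(np.sqrt(-3.0 * slope))
        i0 = float(np.exp(intercept))
        new_mask = q * rg <= qrg_limit
        if new_mask.sum() < min_points:
            raise InsufficientDataError(
                f"fewer than {min_points} points satisfy q*rg <= {qrg_limit}"
            )
        if abs(rg - rg_prev) < 1e-6:
            break
        rg_prev, mask = rg, new_mask
    return rg, i0


@dataclass(frozen=True)
class KratkyCurve:
    x: np.ndarray  # q * rg
    y: np.ndarray  # q^2 I(q) rg^2 / i0


def normalized_kratky(profile: SASProfile, rg: float, i0: float) -> KratkyCurve:
    """Dimensionless Kratky transform q^2 I rg^2 / I0 vs q rg (no smoothing).

    For an ideal Guinier curve the maximum sits at (sqrt(3), 3/e); a bell
    shape indicates a compact, globular scatterer.
    """
    if rg <= 0 or i0 <= 0:
        raise InvalidInputError("rg and i0 must be positive")
    return KratkyCurve(profile.q * rg, profile.q**2 * profile.intensity * rg**2 / i0)


# ---------------------------------------------------------------------------
# Indirect Fourier transform
# ---------------------------------------------------------------------------

def _design_matrix(q: np.ndarray, r_nodes: np.ndarray) -> np.ndarray:
    """IFT kernel A[i, j] = 4 pi \\int phi_j(r) sinc(q_i r) dr over all nodes.

    Hat-function basis on the node grid; element integrals by fixed-order
    Gauss-Legendre quadrature.
    """
    n = r_nodes.size
    gx, gw = leggauss(GAUSS_POINTS_PER_ELEMENT)
    a = np.zeros((q.size, n))
    for k in range(n - 1):
        r0, r1 = r_nodes[k], r_nodes[k + 1]
        h = r1 - r0
        r_g = 0.5 * (r0 + r1) + 0.5 * h * gx  # mapped Gauss points
        w_g = 0.5 * h * gw
        qr = np.outer(q, r_g)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qr == 0, 1.0, np.sin(qr) / qr)
        left = (r1 - r_g) / h  # weight on node k
        right = (r_g - r0) / h  # weight on node k+1
        a[:, k] += 4.0 * np.pi * sinc @ (w_g * left)
        a[:, k + 1] += 4.0 * np.pi * sinc @ (w_g * right)
    return a


def _second_difference(n_free: int) -> np.ndarray:
    """Second-difference operator on the full node vector (zero endpoints),
    restricted to the free interior nodes."""
    n_full = n_free + 2
    d = np.zeros((n_full - 2, n_full))
    for k in range(1, n_full - 1):
        d[k - 1, k - 1 : k + 2] = (1.0, -2.0, 1.0)
    return d[:, 1:-1]  # endpoint columns multiply zeros


def _solve_ift(aw: np.ndarray, yw: np.ndarray, d: np.ndarray, alpha: float):
    stacked = np.vstack([aw, np.sqrt(alpha) * d])
    target = np.concatenate([yw, np.zeros(d.shape[0])])
    coeff, _ = nnls(stacked, target)
    resid = aw @ coeff - yw
    return coeff, float(resid @ resid), float(np.sum((d @ coeff) ** 2))


def _lcurve_alpha(aw, yw, d, n_grid: int = 15) -> float:
    """Regularization weight by L-curve corner (maximum curvature of
    log-residual vs log-penalty over a logarithmic alpha grid)."""
    scale = np.linalg.norm(aw, "fro") ** 2 / max(np.linalg.norm(d, "fro") ** 2, 1e-300)
    alphas = scale * np.logspace(-6, 4, n_grid)
    pts = []
    for alpha in alphas:
        _, chi2, pen = _solve_ift(aw, yw, d, alpha)
        pts.append((np.log(max(chi2, 1e-300)), np.log(max(pen, 1e-300))))
    pts = np.asarray(pts)
    x, y = pts[:, 0], pts[:, 1]
    # finite-difference curvature along the parameterized curve
    t = np.log(alphas)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    ddx, ddy = np.gradient(dx, t), np.gradient(dy, t)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(invalid="ignore", divide="ignore"):
        curv = np.where(denom > 0, np.abs(dx * ddy - dy * ddx) / denom, 0.0)
    return float(alphas[int(np.argmax(curv))])


def ift(profile: SASProfile, d_max: float, alpha: Optional[float] = None,
        n_nodes: int = N_NODES_DEFAULT) -> PairDistanceDistribution:
    """Regularized indirect Fourier transform of a scattering profile.

    Parameters
    ----------
    profile
        Scattering curve with point uncertainties (required for the
        chi-square weighting).
    d_max
        Assumed maximum particle dimension, A (see :func:`choose_dmax`).
    alpha
        Smoothness weight; ``None`` selects it by the L-curve corner over
        a 15-point logarithmic grid.
    n_nodes
        Number of spline nodes on [0, d_max], endpoints pinned to zero.
    """
    if d_max <= 0:
        raise InvalidInputError("d_max must be positive")
    if alpha is not None and alpha < 0:
        raise InvalidInputError("alpha must be nonnegative")
    if profile.sigma is None:
        raise InvalidInputError("the IFT requires point uncertainties")
    if n_nodes < 5:
        raise InvalidInputError("need at least 5 spline nodes")

    r_nodes = np.linspace(0.0, d_max, n_nodes)
    a_full = _design_matrix(profile.q, r_nodes)
    a_free = a_full[:, 1:-1]  # p(0) = p(Dmax) = 0
    aw = a_free / profile.sigma[:, None]
    yw = profile.intensity / profile.sigma
    d = _second_difference(n_nodes - 2)

    if alpha is None:
        alpha = _lcurve_alpha(aw, yw, d)
    coeff, chi2, _ = _solve_ift(aw, yw, d, alpha)

    p = np.zeros(n_nodes)
    p[1:-1] = coeff

    # covariance diagonal of the regularized solution (active-set free)
    sigma_p = None
    try:
        h = aw.T @ aw + alpha * (d.T @ d)
        hinv = np.linalg.pinv(h)
        var = np.sum((hinv @ aw.T) ** 2, axis=1)  # whitened data, unit noise
        sigma_p = np.zeros(n_nodes)
        sigma_p[1:-1] = np.sqrt(np.maximum(var, 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    i0 = float(4.0 * np.pi * np.trapezoid(p, r_nodes))
    rg = _rg_from_pr(r_nodes, p)
    r1 = None
    if np.max(p) > 0:
        try:
            r1 = first_peak_position(r_nodes, p)
        except FeatureNotFoundError:
            r1 = None
    return PairDistanceDistribution(
        r=r_nodes, p=p, d_max=d_max, i0=i0, rg=rg, r1=r1, sigma_p=sigma_p,
        regularization_alpha=float(alpha), fit_chi2=chi2 / len(profile),
    )


def reproject(pd: PairDistanceDistribution, q: np.ndarray) -> np.ndarray:
    """Forward-transform the fitted p(r) back to a model I(q)."""
    a = _design_matrix(np.asarray(q, dtype=float), pd.r)
    return a @ pd.p


# ---------------------------------------------------------------------------
# p(r) statistics and D_max selection
# ---------------------------------------------------------------------------

def first_peak_position(r: np.ndarray, p: np.ndarray) -> float:
    """Location of the first interior local maximum, parabolic-refined."""
    interior = np.where((p[1:-1] >= p[:-2]) & (p[1:-1] > p[2:]))[0] + 1
    # require a strict rise somewhere before to avoid flagging flat starts
    candidates = [i for i in interior if p[i] > 0]
    if not candidates:
        raise FeatureNotFoundError("p(r) has no interior local maximum")
    i = candidates[0]
    if 0 < i < r.size - 1:
        y0, y1, y2 = p[i - 1], p[i], p[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            delta = 0.5 * (y0 - y2) / denom
            return float(r[i] + delta * (r[i + 1] - r[i]))
    return float(r[i])


def pr_statistics(pd: PairDistanceDistribution) -> tuple[float, float, float, float]:
    """(d_max, rg, r1, i0) recomputed from the stored p(r)."""
    rg = _rg_from_pr(pd.r, pd.p)
    i0 = float(4.0 * np.pi * np.trapezoid(pd.p, pd.r))
    r1 = first_peak_position(pd.r, pd.p)
    return pd.d_max, rg, r1, i0


@dataclass
class DmaxScan:
    d_max: float
    table: list  # rows of (candidate, reduced chi2, tail fraction)
    warned: bool = False  # True when no candidate met the selection criteria


def choose_dmax(profile: SASProfile, scan: Sequence[float],
                alpha: Optional[float] = None, n_nodes: int = N_NODES_DEFAULT,
                chi2_slack: float = 0.05, tail_frac: float = 0.02) -> DmaxScan:
    """Scan candidate D_max values and pick the smallest acceptable one.

    A candidate is acceptable when its reduced chi-square is within
    ``chi2_slack`` of the scan minimum and the recovered p(r) decays: the
    mean |p| over the last 5% of r is below ``tail_frac`` of max p (the
    endpoint itself is pinned to zero, so the slope into it is never
    positive for a nonnegative solution).  Falls back to the chi-square
    minimum with a warning flag when nothing qualifies.
    """
    candidates = np.asarray(list(scan), dtype=float)
    if candidates.size < 2:
        raise InvalidInputError("scan needs at least two candidate d_max values")
    rows = []
    for dm in candidates:
        pd = ift(profile, dm, alpha=alpha, n_nodes=n_nodes)
        pmax = float(np.max(pd.p))
        tail = pd.r >= 0.95 * dm
        tail_level = float(np.mean(np.abs(pd.p[tail]))) / pmax if pmax > 0 else 0.0
        rows.append((float(dm), pd.fit_chi2, tail_level))
    chi2s = np.array([r[1] for r in rows])
    best = chi2s.min()
    acceptable = [r for r in rows if r[1] <= best * (1.0 + chi2_slack) and r[2] < tail_frac]
    if acceptable:
        return DmaxScan(min(r[0] for r in acceptable), rows, warned=False)
    return DmaxScan(rows[int(np.argmin(chi2s))][0], rows, warned=True)


def aggregation_number(i0_sample: float, conc_sample: float,
                       i0_monomer_ref: float, conc_ref: float) -> float:
    """Apparent weight-average aggregation number.

    N_agg = (I0_sample / c_sample) / (I0_ref / c_ref): forward scattering
    is proportional to c*M, so the concentration-normalized ratio against
    a monomer reference is the weight-average mass ratio.
    """
    for name, v in (("i0_sample", i0_sample), ("conc_sample", conc_sample),
                    ("i0_monomer_ref", i0_monomer_ref), ("conc_ref", conc_ref)):
        if v <= 0:
            raise InvalidInputError(f"{name} must be positive, got {v}")
    return (i0_sample / conc_sample) / (i0_monomer_ref / conc_ref)


# ---------------------------------------------------------------------------
# Closed forms for validation
# ---------------------------------------------------------------------------

def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized amplitude of a homogeneous sphere, F(0) = 1."""
    qr = np.asarray(q, dtype=float) * radius
    small = qr < 1e-2  # series expansion avoids catastrophic cancellation
    safe = np.where(small, 1.0, qr)
    f = 3.0 * (np.sin(safe) - safe * np.cos(safe)) / safe**3
    return np.where(small, 1.0 - qr**2 / 10.0 + qr**4 / 280.0, f)


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Analytic distance distribution of a solid sphere of diameter D = 2R,
    p(r) proportional to r^2 (1 - 1.5 x + 0.5 x^3), x = r/D, on [0, D]."""
    d = 2.0 * radius
    x = np.asarray(r, dtype=float) / d
    p = r**2 * (1.0 - 1.5 * x + 0.5 * x**3)
    return np.where((x >= 0) & (x <= 1), p, 0.0)
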