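"""Seeded synthetic-data generators with ground-truth records.

Every generator emulates one input class of the pipeline — aromatic
absorbance bands, far-UV CD mixtures, two-state melts, sphere-assembly
scattering curves, Trp emission peaks, exponential lysis decays — and
returns the data object together with a :class:`GroundTruth` record of
every generating parameter, so each analysis stage can be verified by a
round trip.  All randomness flows through ``numpy.random.default_rng``
seeded explicitly: the same seed reproduces the output bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cd import CDBasisSet, SecondaryStructureFractions, synthetic_basis
from .exceptions import InvalidInputError
from .sans import SASProfile, sphere_form_factor
from .spectrum import Spectrum
from .assays import LysisCurve
from .thermal import MeltingCurve, two_state_signal

#: Default heteroscedastic SAS noise model sigma(q) = a*I(q) + b*I(0).
SANS_NOISE_A = 0.02
SANS_NOISE_B = 1e-4

#: Sphere centers (in units of the radius) for each assembly species.
SPECIES_CENTERS = {
    "sphere_monomer": (0.0,),
    "tangent_dimer": (0.0, 2.0),
    "linear_tetramer": (0.0, 2.0, 4.0, 6.0),
}


@dataclass(frozen=True)
class GroundTruth:
    generator: str
    parameters: dict
    seed: Optional[int]

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return str(o)

        return json.dumps(
            {"generator": self.generator, "parameters": self.parameters, "seed": self.seed},
            default=_default, indent=2,
        )


def _rng(seed: Optional[int]) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# UV-vis absorbance
# ---------------------------------------------------------------------------

def gen_absorbance(
    tyr_center: float = 287.0,
    trp_center: float = 295.0,
    tyr_amp: float = 0.5,
    trp_amp: float = 0.45,
    widths: tuple[float, float] = (2.2, 2.2),  # FWHM ~5 nm aromatic fine structure
    baseline: tuple[float, float] = (0.02, 0.0),  # offset, slope per nm
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    grid: tuple[float, float, float] = (250.0, 320.0, 0.5),
) -> tuple[Spectrum, GroundTruth]:
    """Two overlapping aromatic Gaussian bands plus a smooth baseline."""
    for c in (tyr_center, trp_center):
        if not 250 <= c <= 320:
            raise InvalidInputError(f"band center {c} nm outside the 250-320 nm range")
    lo, hi, step = grid
    wl = np.arange(lo, hi + step / 2, step)
    values = (
        tyr_amp * np.exp(-0.5 * ((wl - tyr_center) / widths[0]) ** 2)
        + trp_amp * np.exp(-0.5 * ((wl - trp_center) / widths[1]) ** 2)
        + baseline[0] + baseline[1] * (wl - lo)
    )
    if noise_sd > 0:
        values = values + _rng(seed).normal(0.0, noise_sd, wl.size)
    truth = GroundTruth("gen_absorbance", dict(
        tyr_center=tyr_center, trp_center=trp_center, tyr_amp=tyr_amp, trp_amp=trp_amp,
        widths=widths, baseline=baseline, noise_sd=noise_sd, grid=grid), seed)
    return Spectrum(wl, values, kind="absorbance"), truth


# ---------------------------------------------------------------------------
# Circular dichroism
# ---------------------------------------------------------------------------

def gen_cd(
    fractions: SecondaryStructureFractions,
    scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    basis: Optional[CDBasisSet] = None,
) -> tuple[Spectrum, GroundTruth]:
    """MRE spectrum as a nonnegative mixture of the packaged basis curves.

    ``noise_sd`` is in MRE units (absolute); callers wanting "x% of max"
    should scale accordingly.
    """
    if basis is None:
        basis = synthetic_basis()
    mix = scale * (basis.curves @ fractions.as_array())
    if noise_sd > 0:
        mix = mix + _rng(seed).normal(0.0, noise_sd, mix.size)
    truth = GroundTruth("gen_cd", dict(
        fractions=fractions.as_dict(), scale=scale, noise_sd=noise_sd), seed)
    return Spectrum(basis.wavelengths, mix, kind="mre"), truth


# ---------------------------------------------------------------------------
# Thermal melts
# ---------------------------------------------------------------------------

def gen_melt(
    tm: float = 345.0,
    dh_m: float = 450.0,
    baselines: tuple[float, float, float, float] = (-20.0, -0.01, -2.0, -0.002),
    t_grid: tuple[float, float, float] = (290.0, 380.0, 1.0),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    transitions: Optional[Sequence[tuple[float, float, float]]] = None,
) -> tuple[MeltingCurve, GroundTruth]:
    """Two-state melting curve; optionally a multi-transition mixture.

    ``transitions`` as [(tm_i, dh_i, weight_i), ...] replaces the single
    transition by a weighted sum of two-state fractions sharing the same
    baselines (weights should sum to 1).
    """
    a_n, b_n, a_d, b_d = baselines
    lo, hi, step = t_grid
    t = np.arange(lo, hi + step / 2, step)
    from .units import R_GAS

    if transitions is None:
        y = two_state_signal(t, tm, dh_m, a_n, b_n, a_d, b_d)
    else:
        fd = np.zeros_like(t)
        for tm_i, dh_i, w_i in transitions:
            k = np.exp(-(dh_i / R_GAS) * (1.0 / t - 1.0 / tm_i))
            fd += w_i * k / (1.0 + k)
        y = (a_n + b_n * t) * (1 - fd) + (a_d + b_d * t) * fd
    if noise_sd > 0:
        y = y + _rng(seed).normal(0.0, noise_sd, t.size)
    truth = GroundTruth("gen_melt", dict(
        tm=tm, dh_m=dh_m, baselines=baselines, t_grid=t_grid,
        noise_sd=noise_sd, transitions=transitions), seed)
    return MeltingCurve(t, y), truth


# ---------------------------------------------------------------------------
# Small-angle scattering
# ---------------------------------------------------------------------------

def assembly_intensity(q: np.ndarray, species: str, radius: float) -> np.ndarray:
    """Normalized (P(0) = 1) orientation-averaged intensity of a rigid
    assembly of tangent spheres, via the Debye formula over centers."""
    if species not in SPECIES_CENTERS:
        raise InvalidInputError(f"unknown species {species!r}; expected {sorted(SPECIES_CENTERS)}")
    centers = np.asarray(SPECIES_CENTERS[species]) * radius
    n = centers.size
    f2 = sphere_form_factor(q, radius) ** 2
    s = np.zeros_like(q)
    for i in range(n):
        for j in range(n):
            d = abs(centers[i] - centers[j])
            if d == 0:
                s += 1.0
            else:
                qd = q * d
                with np.errstate(invalid="ignore", divide="ignore"):
                    s += np.where(qd == 0, 1.0, np.sin(qd) / qd)
    return f2 * s / n**2


def gen_sans(
    components: Sequence[tuple[str, float, float]] = (("sphere_monomer", 30.0, 1.0),),
    background: float = 0.0,
    noise: tuple[float, float] = (SANS_NOISE_A, SANS_NOISE_B),
    q_grid: tuple[float, float, int] = (0.006, 0.45, 120),
    seed: Optional[int] = None,
    scale: float = 100.0,
    concentration: float = 1.0,
    add_noise: bool = True,
) -> tuple[SASProfile, GroundTruth]:
    """Scattering curve of a mass-weighted mixture of sphere assemblies.

    ``components`` lists (species, radius A, mass weight); weights must be
    nonnegative and sum to 1.  The mixture intensity is
    I(q) = scale * c * sum_i w_i (M_i/M_1) P_i(q) + background, so the
    concentration-normalized forward scattering relative to a monomer at
    the same ``scale`` equals the weight-average mass ratio (the ground
    truth for the aggregation number).  sigma(q) = a*I(q) + b*I(0); with
    ``add_noise`` the intensities receive seeded Gaussian noise of that
    width (log-spaced q grid, as measured profiles are binned).
    """
    weights = np.array([w for _, _, w in components], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise InvalidInputError("component mass weights must be >= 0 and sum to 1")
    lo, hi, n_q = q_grid
    q = np.geomspace(lo, hi, int(n_q))
    i_model = np.zeros_like(q)
    for species, radius, w in components:
        n_spheres = len(SPECIES_CENTERS[species])
        i_model += w * n_spheres * assembly_intensity(q, species, radius)
    i_model = scale * concentration * i_model + background
    i0_model = scale * concentration * float(
        sum(w * len(SPECIES_CENTERS[sp]) for sp, _, w in components)) + background
    sigma = noise[0] * np.abs(i_model) + noise[1] * i0_model
    intensity = i_model
    if add_noise:
        intensity = i_model + _rng(seed).normal(0.0, 1.0, q.size) * sigma
    truth = GroundTruth("gen_sans", dict(
        components=list(components), background=background, noise=noise, q_grid=q_grid,
        scale=scale, concentration=concentration,
        i0=i0_model, i0_per_conc=i0_model / concentration,
        n_agg=float(sum(w * len(SPECIES_CENTERS[sp]) for sp, _, w in components))), seed)
    return SASProfile(q, intensity, sigma, concentration=concentration), truth


# ---------------------------------------------------------------------------
# Trp emission
# ---------------------------------------------------------------------------

def gen_emission(
    mode_nm: float = 338.0,
    width: float = 18.0,
    asymmetry: float = 0.0,
    amplitude: float = 1000.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    grid: tuple[float, float, float] = (305.0, 380.0, 0.5),
) -> tuple[Spectrum, GroundTruth]:
    """Log-normal-shaped emission peak with its mode exactly at ``mode_nm``.

    The profile is exp(-ln^2(u) / (2 s^2)) with u = 1 + s*(lambda-mode)/w;
    the symmetric Gaussian is recovered as asymmetry -> 0, and the peak
    maximum sits at ``mode_nm`` for every asymmetry.
    """
    lo, hi, step = grid
    wl = np.arange(lo, hi + step / 2, step)
    s = asymmetry
    if s == 0:
        shape = np.exp(-0.5 * ((wl - mode_nm) / width) ** 2)
    else:
        u = 1.0 + s * (wl - mode_nm) / width
        shape = np.where(u > 0, np.exp(-0.5 * (np.log(np.where(u > 0, u, 1.0)) / s) ** 2), 0.0)
    values = amplitude * shape
    if noise_sd > 0:
        values = values + _rng(seed).normal(0.0, noise_sd, wl.size)
    truth = GroundTruth("gen_emission", dict(
        mode_nm=mode_nm, width=width, asymmetry=asymmetry, amplitude=amplitude,
        noise_sd=noise_sd, grid=grid), seed)
    return Spectrum(wl, values, kind="emission"), truth


# ---------------------------------------------------------------------------
# Lysis curves
# ---------------------------------------------------------------------------

def gen_lysis(
    a0: float = 0.8,
    rate_constant: float = 0.05,  # 1/min
    plateau: float = 0.2,
    noise_sd: float = 0.0,
    t_grid: tuple[float, float, float] = (0.0, 10.0, 0.1),
    enzyme_mass: float = 1.0,
    seed: Optional[int] = None,
) -> tuple[LysisCurve, GroundTruth]:
    """Exponential turbidity decay A(t) = plateau + a0 * exp(-k t).

    The true initial rate is a0 * k (AU/min).
    """
    lo, hi, step = t_grid
    t = np.arange(lo, hi + step / 2, step)
    a = plateau + a0 * np.exp(-rate_constant * t)
    if noise_sd > 0:
        a = a + _rng(seed).normal(0.0, noise_sd, t.size)
    truth = GroundTruth("gen_lysis", dict(
        a0=a0, rate_constant=rate_constant, plateau=plateau, noise_sd=noise_sd,
        t_grid=t_grid, enzyme_mass=enzyme_mass, initial_rate=a0 * rate_constant), seed)
    return LysisCurve(t, a, enzyme_mass=enzyme_mass), truth
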