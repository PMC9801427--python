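"""Far-UV circular dichroism: mean residue ellipticity and secondary-structure
deconvolution.

The measured ellipticity (mdeg) is normalized per residue to mean residue
ellipticity (MRE, deg cm^2 dmol^-1 residue^-1) and decomposed over a basis
of reference motif spectra (alpha-helix, beta-sheet, turn, unordered) by
nonnegative least squares over 200-250 nm, with the coefficients
renormalized to fractions summing to one.  This is a generic basis-set
deconvolution, not a re-implementation of any particular published
program's reference set or algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .exceptions import InvalidInputError
from .spectrum import Spectrum

MOTIFS = ("alpha", "beta", "turn", "unordered")
FIT_RANGE = (200.0, 250.0)

#: Below this reference fraction a fold change is reported as an absolute
#: difference instead of a ratio.
FOLD_CHANGE_FLOOR = 0.01


@dataclass(frozen=True)
class SecondaryStructureFractions:
    alpha: float
    beta: float
    turn: float
    unordered: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise InvalidInputError("fractions must lie in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise InvalidInputError(f"fractions must sum to 1, got {arr.sum():.8f}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.turn, self.unordered])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(MOTIFS, self.as_array().tolist()))


@dataclass
class CDBasisSet:
    """Reference MRE curves, one per motif, on a shared wavelength grid."""

    wavelengths: np.ndarray  # nm
    curves: np.ndarray  # shape (n_wavelengths, 4), columns ordered as MOTIFS

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.shape != (self.wavelengths.size, len(MOTIFS)):
            raise InvalidInputError(
                f"basis must be (n_wavelengths, {len(MOTIFS)}); got {self.curves.shape}"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise InvalidInputError("basis wavelengths must be strictly increasing")

    def covers(self, fit_range: tuple[float, float]) -> bool:
        return self.wavelengths[0] <= fit_range[0] and self.wavelengths[-1] >= fit_range[1]

    def interpolated(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [np.interp(wavelengths, self.wavelengths, self.curves[:, j]) for j in range(len(MOTIFS))]
        )

    def motif_spectrum(self, motif: str) -> Spectrum:
        return Spectrum(self.wavelengths, self.curves[:, MOTIFS.index(motif)], kind="mre")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curves, columns=list(MOTIFS)).assign(wavelength_nm=self.wavelengths)[
            ["wavelength_nm", *MOTIFS]
        ]

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CDBasisSet":
        df = pd.read_csv(path)
        missing = [m for m in MOTIFS if m not in df.columns]
        if missing:
            raise InvalidInputError(f"basis file lacks motif columns {missing}")
        return cls(df["wavelength_nm"].to_numpy(), df[list(MOTIFS)].to_numpy())


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def synthetic_basis(lo: float = 200.0, hi: float = 250.0, step: float = 0.5) -> CDBasisSet:
    """Idealized four-motif reference set built from Gaussian lobes.

    Band positions follow the canonical far-UV CD signatures: the
    alpha-helix double minimum at 208/222 nm with a strong positive band
    near 192 nm (truncated at the 200 nm edge); the beta-sheet minimum
    near 216 nm with a positive band near 196 nm; a weak turn spectrum;
    and the unordered deep negative band near 198 nm.  Amplitudes are on
    the deg cm^2 dmol^-1 scale typical of fully formed motifs.  This is a
    synthetic stand-in for an experimentally derived reference set and is
    intended for simulation and self-consistent testing, not for
    quantitative analysis of measured spectra.
    """
    wl = np.arange(lo, hi + step / 2, step)
    alpha = 70e3 * _gauss(wl, 192, 8) - 30e3 * _gauss(wl, 208, 7) - 33e3 * _gauss(wl, 222, 9)
    beta = 35e3 * _gauss(wl, 196, 7) - 18e3 * _gauss(wl, 216, 9)
    turn = 12e3 * _gauss(wl, 205, 8) - 4e3 * _gauss(wl, 225, 11)
    unordered = -42e3 * _gauss(wl, 198, 9) + 2.5e3 * _gauss(wl, 218, 14)
    return CDBasisSet(wl, np.column_stack([alpha, beta, turn, unordered]))


def mean_residue_ellipticity(
    raw: Spectrum,
    conc_molar: float,
    path_cm: float,
    n_residues: int,
    *,
    per_bond: bool = False,
) -> Spectrum:
    """Convert raw ellipticity (mdeg) to mean residue ellipticity.

    [theta] = theta_mdeg / (10 * path_cm * conc_molar * N), with N the
    residue count (or the peptide-bond count ``n_residues - 1`` when
    ``per_bond`` is set; instrument-vendor conventions differ).
    """
    if raw.kind != "ellipticity":
        raise InvalidInputError(f"expected a raw ellipticity spectrum, got kind={raw.kind!r}")
    if conc_molar <= 0 or path_cm <= 0:
        raise InvalidInputError("concentration and path length must be positive")
    if n_residues < 2:
        raise InvalidInputError("n_residues must be >= 2")
    n = n_residues - 1 if per_bond else n_residues
    mre = raw.values / (10.0 * path_cm * conc_molar * n)
    return Spectrum(raw.wavelengths, mre, kind="mre", metadata=dict(raw.metadata))


@dataclass(frozen=True)
class DeconvolutionResult:
    fractions: SecondaryStructureFractions
    residual_rms: float  # in MRE units, over the fit range
    scale: float  # sum of raw NNLS coefficients (absolute-scale factor)


def deconvolve(
    mre: Spectrum,
    basis: CDBasisSet | None = None,
    fit_range: tuple[float, float] = FIT_RANGE,
) -> DeconvolutionResult:
    """Nonnegative least-squares decomposition of an MRE spectrum.

    Coefficients are renormalized to sum to one, so the result is
    invariant to positive rescaling of the input (robust to calibration
    errors in absolute scale).
    """
    if basis is None:
        basis = synthetic_basis()
    if mre.kind not in ("mre", "ellipticity"):
        raise InvalidInputError(f"expected an (MRE) ellipticity spectrum, got kind={mre.kind!r}")
    if not mre.covers(fit_range):
        raise InvalidInputError(f"spectrum does not cover the fit range {fit_range}")
    if not basis.covers(fit_range):
        raise InvalidInputError(f"basis does not cover the fit range {fit_range}")
    sub = mre.crop(fit_range)
    a = basis.interpolated(sub.wavelengths)
    if np.linalg.matrix_rank(a) < len(MOTIFS):
        raise InvalidInputError("basis curves are linearly dependent over the fit range")
    coeff, rnorm = nnls(a, sub.values)
    total = coeff.sum()
    if total <= 0:
        raise InvalidInputError("deconvolution degenerate: no motif receives positive weight")
    fracs = SecondaryStructureFractions(*(coeff / total))
    return DeconvolutionResult(fracs, float(rnorm / np.sqrt(len(sub))), float(total))


@dataclass(frozen=True)
class MotifChange:
    value: float
    mode: str  # "ratio" (fold change) or "absolute" (difference)


def fold_change(
    sample: SecondaryStructureFractions,
    reference: SecondaryStructureFractions,
    floor: float = FOLD_CHANGE_FLOOR,
) -> dict[str, MotifChange]:
    """Per-motif fold change sample/reference.

    Motifs whose reference fraction is below ``floor`` are reported as
    absolute differences (flagged ``mode="absolute"``) since a ratio
    against a near-zero reference is not meaningful.
    """
    out: dict[str, MotifChange] = {}
    s, r = sample.as_dict(), reference.as_dict()
    for motif in MOTIFS:
        if r[motif] < floor:
            out[motif] = MotifChange(s[motif] - r[motif], "absolute")
        else:
            out[motif] = MotifChange(s[motif] / r[motif], "ratio")
    return out
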