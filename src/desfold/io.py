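"""Delimited-text readers and writers for the pipeline's data types.

All readers accept the common lab-export dialects: comma- or
whitespace-separated columns, ``#``/``;``/``%``/``!`` comment or header
lines, and either LF or CRLF line endings.  Parse errors carry the
offending line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from .assays import LysisCurve
from .exceptions import InvalidInputError
from .sans import PairDistanceDistribution, SASProfile
from .spectrum import Spectrum
from .thermal import MeltingCurve
from .units import celsius_to_kelvin

COMMENT_CHARS = ("#", ";", "%", "!")


def _parse_columns(path: str | Path, min_cols: int) -> np.ndarray:
    """Parse numeric columns; skips comment lines and a header line."""
    rows: list[list[float]] = []
    n_cols = None
    with open(path, "r", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(COMMENT_CHARS):
                continue
            fields = line.replace(",", " ").split()
            try:
                values = [float(x) for x in fields]
            except ValueError:
                if not rows:  # tolerate a single textual header row
                    continue
                raise InvalidInputError(f"{path}: malformed numeric row at line {lineno}: {line!r}")
            if n_cols is None:
                n_cols = len(values)
                if n_cols < min_cols:
                    raise InvalidInputError(
                        f"{path}: line {lineno} has {n_cols} columns; need >= {min_cols}")
            elif len(values) != n_cols:
                raise InvalidInputError(
                    f"{path}: inconsistent column count at line {lineno}")
            rows.append(values)
    if not rows:
        raise InvalidInputError(f"{path}: no data rows found")
    return np.asarray(rows, dtype=float)


def read_spectrum(path: str | Path, kind: str = "absorbance") -> Spectrum:
    """Two-column (wavelength, value) or three-column (+uncertainty) file."""
    data = _parse_columns(path, 2)
    unc = data[:, 2] if data.shape[1] >= 3 else None
    return Spectrum(data[:, 0], data[:, 1], uncertainties=unc, kind=kind)


def read_sas_profile(path: str | Path, concentration: Optional[float] = None) -> SASProfile:
    """Three-column (q, I, sigma) SAS profile in the common .dat dialect."""
    data = _parse_columns(path, 2)
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SASProfile(data[:, 0], data[:, 1], sigma, concentration=concentration)


def read_melting_curve(path: str | Path, celsius: bool = False) -> MeltingCurve:
    data = _parse_columns(path, 2)
    t = celsius_to_kelvin(data[:, 0]) if celsius else data[:, 0]
    unc = data[:, 2] if data.shape[1] >= 3 else None
    return MeltingCurve(t, data[:, 1], uncertainties=unc)


def read_lysis_curve(path: str | Path, enzyme_mass: float = 1.0) -> LysisCurve:
    data = _parse_columns(path, 2)
    return LysisCurve(data[:, 0], data[:, 1], enzyme_mass=enzyme_mass)


def _write_columns(path: str | Path, header: str, columns: list[np.ndarray]) -> None:
    arr = np.column_stack(columns)
    np.savetxt(path, arr, header=header, fmt="%.12g")


def write_spectrum(path: str | Path, s: Spectrum) -> None:
    cols = [s.wavelengths, s.values]
    header = "wavelength_nm value"
    if s.uncertainties is not None:
        cols.append(s.uncertainties)
        header += " uncertainty"
    _write_columns(path, header, cols)


def write_sas_profile(path: str | Path, p: SASProfile) -> None:
    cols = [p.q, p.intensity]
    header = "q_invA intensity"
    if p.sigma is not None:
        cols.append(p.sigma)
        header += " sigma"
    _write_columns(path, header, cols)


def write_melting_curve(path: str | Path, m: MeltingCurve) -> None:
    cols = [m.temperatures, m.signal]
    header = "temperature_K signal"
    if m.uncertainties is not None:
        cols.append(m.uncertainties)
        header += " uncertainty"
    _write_columns(path, header, cols)


def write_lysis_curve(path: str | Path, c: LysisCurve) -> None:
    _write_columns(path, "time_min a450", [c.time, c.a450])


def write_pr(path: str | Path, pd: PairDistanceDistribution) -> None:
    """p(r) as an (r, p, sigma_p) table."""
    sigma = pd.sigma_p if pd.sigma_p is not None else np.zeros_like(pd.p)
    _write_columns(path, "r_A p sigma_p", [pd.r, pd.p, sigma])
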