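"""Deep-eutectic-solvent composition bookkeeping.

Hydrated DESs are described in the 1:2:n mole-ratio notation
(salt : hydrogen-bond donor : water); ``n`` parameterizes hydration.
This module converts between ``n`` and weight percent water, the x-axis
on which every downstream observable is plotted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .exceptions import InvalidInputError

# Default molar masses, g/mol (IUPAC 2021 atomic weights, 2 d.p.)
CHOLINE_CHLORIDE_MM = 139.62
GLYCEROL_MM = 92.09
UREA_MM = 60.06
WATER_MM = 18.015

#: Residual (remanent) water mole ratio measured in the nominally dry DESs.
RESIDUAL_WATER_N = {"glycerol": 0.065, "urea": 0.034}


class LabelMismatchWarning(UserWarning):
    """A user-stated wt % label disagrees with the computed value."""


@dataclass(frozen=True)
class SolventComposition:
    """A 1:2:n salt:HBD:water mixture.

    The salt and HBD mole numbers are fixed at 1 and 2 by the notation;
    ``water_moles`` is the hydration parameter n.  ``stated_wt_percent``
    optionally carries a label quoted from an external source verbatim;
    it is preserved but never substituted for the computed value.
    """

    water_moles: float
    hbd_molar_mass: float
    salt_molar_mass: float = CHOLINE_CHLORIDE_MM
    water_molar_mass: float = WATER_MM
    salt_moles: float = 1.0
    hbd_moles: float = 2.0
    label: str | None = None
    stated_wt_percent: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.water_moles < 0:
            raise InvalidInputError(f"water mole ratio n must be >= 0, got {self.water_moles}")
        for name in ("hbd_molar_mass", "salt_molar_mass", "water_molar_mass"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")

    @property
    def anhydrous_mass(self) -> float:
        """Mass of one formula unit of the dry DES, g/mol."""
        return self.salt_moles * self.salt_molar_mass + self.hbd_moles * self.hbd_molar_mass

    def with_n(self, n: float) -> "SolventComposition":
        return replace(self, water_moles=n, stated_wt_percent=None)


def glycerol_des(n: float, *, include_residual: bool = False,
                 label: str | None = None,
                 stated_wt_percent: float | None = None) -> SolventComposition:
    """1:2:n choline chloride : glycerol : water."""
    if include_residual:
        n = n + RESIDUAL_WATER_N["glycerol"]
    return SolventComposition(n, GLYCEROL_MM, label=label or f"1:2:{n:g} ChCl:Glyc:H2O",
                              stated_wt_percent=stated_wt_percent)


def urea_des(n: float, *, include_residual: bool = False,
             label: str | None = None,
             stated_wt_percent: float | None = None) -> SolventComposition:
    """1:2:n choline chloride : urea : water."""
    if include_residual:
        n = n + RESIDUAL_WATER_N["urea"]
    return SolventComposition(n, UREA_MM, label=label or f"1:2:{n:g} ChCl:Urea:H2O",
                              stated_wt_percent=stated_wt_percent)


def wt_percent_water(comp: SolventComposition, *, label_tolerance: float = 0.2) -> float:
    """Weight percent water of a 1:2:n composition.

    100 * n*M_w / (M_salt + 2*M_hbd + n*M_w).  Strictly increasing in n,
    bounded in [0, 100).  If the composition carries a stated wt % label
    that disagrees with the computed value by more than ``label_tolerance``
    percentage points, a :class:`LabelMismatchWarning` is emitted (the
    label is preserved, not overwritten).
    """
    water_mass = comp.water_moles * comp.water_molar_mass
    wt = 100.0 * water_mass / (comp.anhydrous_mass + water_mass)
    if comp.stated_wt_percent is not None and abs(wt - comp.stated_wt_percent) > label_tolerance:
        warnings.warn(
            f"stated label {comp.stated_wt_percent} wt % differs from computed "
            f"{wt:.2f} wt % by more than {label_tolerance} points",
            LabelMismatchWarning,
            stacklevel=2,
        )
    return wt


def water_mole_ratio(wt_percent: float, comp: SolventComposition) -> float:
    """Invert :func:`wt_percent_water`: the n giving the requested wt %.

    Closed-form algebraic inverse; ``comp.water_moles`` is ignored.
    """
    if not 0 <= wt_percent < 100:
        raise InvalidInputError(f"wt % water must be in [0, 100), got {wt_percent}")
    return wt_percent * comp.anhydrous_mass / (comp.water_molar_mass * (100.0 - wt_percent))
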