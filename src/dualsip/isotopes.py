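"""Stable-isotope arithmetic shared by every analysis stage.

Deltas (per-mil vs. VPDB for carbon, VSMOW for hydrogen) exist only at the
I/O boundary; internally all mixing and rate math runs on atom fractions,
which are linear under mass balance. Exact isotope masses provide the
mass-shift constants used by the isotopologue matcher.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

Element = Literal["C", "H"]
Standard = Literal["VPDB", "VSMOW"]

#: Hydrogens added per fatty acid during methyl esterification (CH3 replaces OH's H,
#: net +CH2 on the acid but the standard FAME bookkeeping adds one C and three H
#: to the measured molecule relative to the free fatty acid's C/H inventories).
_ADDED_ATOMS = {"C": 1, "H": 3}


class IsotopeError(ValueError):
    """Base class for isotope-domain errors."""


class InvalidDeltaError(IsotopeError):
    """Delta value at or below -1000 permil implies a non-positive ratio."""


class InvalidRatioError(IsotopeError):
    """Isotope ratios must be non-negative."""


class IncompatibleDeltaError(IsotopeError):
    """Two deltas combined arithmetically must share element and standard."""


@dataclass(frozen=True)
class IsotopeConstants:
    """Reference ratios and exact atomic masses.

    Defaults are the IUPAC/CIAAW values: R_VPDB for 13C/12C, R_VSMOW for D/H,
    and exact masses in Da. All fields can be overridden (e.g. for sensitivity
    studies); results files should echo the constants used.
    """

    r_vpdb_13c: float = 0.0111802
    r_vsmow_d: float = 1.5576e-4
    mass_12c: float = 12.0
    mass_13c: float = 13.00335484
    mass_1h: float = 1.00782503
    mass_2h: float = 2.01410178

    def __post_init__(self) -> None:
        for name in ("r_vpdb_13c", "r_vsmow_d", "mass_12c", "mass_13c",
                     "mass_1h", "mass_2h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 1.0030 < self.mass_shift_13c < 1.0037:
            raise ValueError("13C-12C mass difference outside physical range")
        if not 1.0059 < self.mass_shift_d < 1.0066:
            raise ValueError("2H-1H mass difference outside physical range")

    @property
    def mass_shift_13c(self) -> float:
        """Mass added per 12C -> 13C substitution (~1.0034 Da)."""
        return self.mass_13c - self.mass_12c

    @property
    def mass_shift_d(self) -> float:
        """Mass added per 1H -> 2H substitution (~1.0063 Da)."""
        return self.mass_2h - self.mass_1h

    def reference_ratio(self, element: Element) -> float:
        return self.r_vpdb_13c if element == "C" else self.r_vsmow_d

    def as_dict(self) -> dict[str, float]:
        return {
            "r_vpdb_13c": self.r_vpdb_13c,
            "r_vsmow_d": self.r_vsmow_d,
            "mass_12c": self.mass_12c,
            "mass_13c": self.mass_13c,
            "mass_1h": self.mass_1h,
            "mass_2h": self.mass_2h,
        }


DEFAULT_CONSTANTS = IsotopeConstants()


@dataclass(frozen=True)
class DeltaValue:
    """An isotope delta in per mil against a named standard."""

    value: float
    element: Element
    standard: Standard

    def __post_init__(self) -> None:
        if self.value <= -1000.0:
            raise InvalidDeltaError(
                f"delta {self.value} permil implies a non-positive isotope ratio"
            )
        expected = "VPDB" if self.element == "C" else "VSMOW"
        if self.standard != expected:
            raise IncompatibleDeltaError(
                f"element {self.element} must be reported against {expected}"
            )


@dataclass(frozen=True)
class AtomFraction:
    """Fraction of the heavy isotope among all atoms of an element (0-1)."""

    value: float
    element: Element

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"atom fraction {self.value} outside [0, 1]")


def delta13c(value: float) -> DeltaValue:
    return DeltaValue(value, "C", "VPDB")


def delta_d(value: float) -> DeltaValue:
    return DeltaValue(value, "H", "VSMOW")


def delta_to_ratio(d: DeltaValue, consts: IsotopeConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a delta to an absolute isotope ratio R = R_std * (1 + d/1000)."""
    return consts.reference_ratio(d.element) * (1.0 + d.value / 1000.0)


def ratio_to_delta(r: float, element: Element,
                   consts: IsotopeConstants = DEFAULT_CONSTANTS) -> DeltaValue:
    """Inverse of :func:`delta_to_ratio`."""
    if r <= 0:
        raise InvalidRatioError(f"ratio {r} must be positive to express a delta")
    standard: Standard = "VPDB" if element == "C" else "VSMOW"
    return DeltaValue((r / consts.reference_ratio(element) - 1.0) * 1000.0,
                      element, standard)


def ratio_to_atom_fraction(r: float, element: Element = "C") -> AtomFraction:
    """F = R / (1 + R): heavy atoms as a fraction of all atoms of the element."""
    if r < 0:
        raise InvalidRatioError(f"ratio {r} is negative")
    return AtomFraction(r / (1.0 + r), element)


def atom_fraction_to_ratio(f: AtomFraction) -> float:
    if f.value >= 1.0:
        raise InvalidRatioError("atom fraction 1 has no finite ratio")
    return f.value / (1.0 - f.value)


def delta_to_atom_fraction(d: DeltaValue,
                           consts: IsotopeConstants = DEFAULT_CONSTANTS) -> AtomFraction:
    return ratio_to_atom_fraction(delta_to_ratio(d, consts), d.element)


def methylation_correct(delta_fame: DeltaValue, n_fa_atoms: int,
                        delta_agent: DeltaValue) -> DeltaValue:
    """Remove the derivatization offset from a FAME delta by mass balance.

    Methylation adds one carbon (three hydrogens) from the derivatizing agent
    to each fatty acid. With ``n`` analyte atoms and ``a`` added atoms the FAME
    delta is the atom-weighted mean, so the free fatty acid delta is

        delta_FA = ((n + a) * delta_FAME - a * delta_agent) / n

    The delta scale is treated as linear for mixing, the standard approximation
    at natural through moderately enriched compositions.

    Parameters
    ----------
    delta_fame : measured delta of the methyl ester.
    n_fa_atoms : number of analyte atoms (C or H, matching the deltas' element)
        in the underivatized fatty acid; must be >= 1.
    delta_agent : delta of the derivatizing agent (e.g. the methanol used),
        same element and standard.
    """
    if n_fa_atoms < 1:
        raise ValueError("fatty acid must contribute at least one atom")
    if (delta_fame.element != delta_agent.element
            or delta_fame.standard != delta_agent.standard):
        raise IncompatibleDeltaError(
            "FAME and derivatizing-agent deltas must share element and standard"
        )
    a = _ADDED_ATOMS[delta_fame.element]
    n = n_fa_atoms
    corrected = ((n + a) * delta_fame.value - a * delta_agent.value) / n
    return replace(delta_fame, value=corrected)


def excess_atom_fraction(labeled: DeltaValue, baseline: DeltaValue,
                         consts: IsotopeConstants = DEFAULT_CONSTANTS) -> float:
    """Excess atom fraction of label: F(labeled) - F(baseline).

    May be negative (apparent label loss); callers decide whether to clamp.
    Returned as a bare float because a signed quantity is not an AtomFraction.
    """
    if (labeled.element != baseline.element
            or labeled.standard != baseline.standard):
        raise IncompatibleDeltaError(
            "labeled and baseline deltas must share element and standard"
        )
    f_l = delta_to_atom_fraction(labeled, consts).value
    f_b = delta_to_atom_fraction(baseline, consts).value
    return f_l - f_b
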