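"""PLFA-SIP: nomenclature parsing, label-incorporation rates, Ra/Rt calls.

Compound-specific isotope data for phospholipid fatty acids (PLFAs) at the
start (T0) and end (Tend) of an incubation are turned into per-lipid label
incorporation rates

    rate = dF * C_produced / t        [pmol isotope / L / day]

where dF is the increase in the heavy-isotope atom fraction of the lipid
between T0 and Tend and C_produced = (conc_Tend - conc_T0) * n_carbons is the
carbon newly fixed into that lipid pool. In a dual-label incubation the 13C
rate (from 13C-DIC) gives inorganic-carbon assimilation Ra and the D rate
(from the deuterated organic substrate) tracks total lipid production Rt; the
ratio Ra/Rt discriminates predominantly heterotrophic (<= 0.3) from
essentially autotrophic (~1) lipid production.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Optional

from .isotopes import (
    AtomFraction,
    DeltaValue,
    IsotopeConstants,
    DEFAULT_CONSTANTS,
    excess_atom_fraction,
)

Isotope = Literal["13C", "D"]
Timepoint = Literal["T0", "Tend"]

HETEROTROPHIC_MAX = 0.3   # Ra/Rt at or below: predominantly heterotrophic
AUTOTROPHIC_MIN = 0.8     # Ra/Rt at or above: essentially autotrophic


class PlfaError(ValueError):
    pass


class NomenclatureError(PlfaError):
    pass


class PairingError(PlfaError):
    """T0/Tend measurements do not describe the same lipid."""


class UndefinedRatioError(PlfaError):
    """Total-production rate Rt is zero; Ra/Rt is undefined."""


# grammar: [<pos>Me|cy|i|a] [C] <chain>:<db> [w<pos>] [c|t]
_NAME_RE = re.compile(
    r"^(?:(?P<mepos>\d+)Me|(?P<prefix>cy|i|a))?"
    r"C?(?P<chain>\d+):(?P<db>\d+)"
    r"(?:[wω](?P<omega>\d+))?"
    r"(?P<geom>[ct])?$",
    re.IGNORECASE,
)


@dataclass(frozen=True)
class PlfaName:
    """A parsed PLFA name in standard nomenclature.

    ``n_carbons`` counts all carbons of the free fatty acid including branch
    methyls: the chain number before the colon plus one for a mid-chain methyl
    ("10Me16:0" has 17 C). iso/anteiso/cyclopropane names already count every
    carbon in the chain number. ``n_hydrogens`` follows C_nH_(2n-2u)O2 with one
    degree of unsaturation per double bond or cyclopropane ring.
    """

    raw: str
    n_carbons: int
    n_double_bonds: int
    omega_position: Optional[int] = None
    methyl_position: Optional[int] = None
    prefix: Optional[str] = None  # one of {"cy", "i", "a"} or None

    def __post_init__(self) -> None:
        if not 10 <= self.n_carbons <= 24:
            raise NomenclatureError(
                f"{self.raw!r}: carbon count {self.n_carbons} outside [10, 24]"
            )
        if not 0 <= self.n_double_bonds <= 6:
            raise NomenclatureError(
                f"{self.raw!r}: {self.n_double_bonds} double bonds outside [0, 6]"
            )
        if self.omega_position is not None and self.n_double_bonds < 1:
            raise NomenclatureError(
                f"{self.raw!r}: omega position requires at least one double bond"
            )

    @property
    def n_hydrogens(self) -> int:
        rings = 1 if self.prefix == "cy" else 0
        return 2 * self.n_carbons - 2 * (self.n_double_bonds + rings)

    def canonical(self) -> str:
        parts = []
        if self.methyl_position is not None:
            parts.append(f"{self.methyl_position}Me")
        elif self.prefix:
            parts.append(self.prefix)
        chain = self.n_carbons - (1 if self.methyl_position is not None else 0)
        parts.append(f"{chain}:{self.n_double_bonds}")
        if self.omega_position is not None:
            parts.append(f"w{self.omega_position}")
        return "".join(parts)


def parse_plfa_name(raw: str) -> PlfaName:
    """Parse standard PLFA nomenclature.

    Accepted grammar: ``[<pos>Me | cy | i | a] [C] <chain>:<double_bonds>
    [w<pos> | ω<pos>] [c | t]``, e.g. ``16:0``, ``a15:0``, ``C18:1w7``,
    ``10Me16:0``, ``cy17:0``. The optional cis/trans letter is accepted and
    ignored for mass bookkeeping.
    """
    if not raw or not raw.strip():
        raise NomenclatureError("empty PLFA name")
    m = _NAME_RE.match(raw.strip())
    if m is None:
        raise NomenclatureError(
            f"cannot parse {raw!r}; expected e.g. '16:0', 'a15:0', "
            f"'C18:1w7', '10Me16:0', 'cy17:0'"
        )
    chain = int(m.group("chain"))
    mepos = m.group("mepos")
    prefix = m.group("prefix")
    n_carbons = chain + (1 if mepos else 0)
    return PlfaName(
        raw=raw.strip(),
        n_carbons=n_carbons,
        n_double_bonds=int(m.group("db")),
        omega_position=int(m.group("omega")) if m.group("omega") else None,
        methyl_position=int(mepos) if mepos else None,
        prefix=prefix.lower() if prefix else None,
    )


@dataclass(frozen=True)
class PlfaMeasurement:
    """One lipid at one timepoint: concentration plus dual isotope deltas."""

    name: PlfaName
    timepoint: Timepoint
    concentration: float  # pmol lipid / L
    delta_13c: DeltaValue
    delta_d: DeltaValue
    treatment: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise PlfaError("concentration must be >= 0")


@dataclass(frozen=True)
class ProductionRate:
    name: PlfaName
    isotope: Isotope
    rate: float  # pmol isotope / L / day
    c_produced: float  # pmol C/L (or pmol H/L in element-consistent D mode)
    delta_f: float  # excess atom fraction, signed
    clamped: bool


@dataclass(frozen=True)
class TrophicCall:
    name: PlfaName
    ra: float
    rt: float
    ra_rt: float
    call: Literal["heterotrophic", "mixed", "autotrophic"]


def carbon_produced(t0: PlfaMeasurement, tend: PlfaMeasurement) -> float:
    """Carbon newly present in the lipid pool: (conc_Tend - conc_T0) * n_C.

    Negative values (net lipid loss) are returned as-is at this layer.
    """
    if t0.name.canonical() != tend.name.canonical():
        raise PairingError(
            f"cannot pair {t0.name.raw!r} (T0) with {tend.name.raw!r} (Tend)"
        )
    return (tend.concentration - t0.concentration) * t0.name.n_carbons


def incorporation_rate(t0: PlfaMeasurement, tend: PlfaMeasurement,
                       isotope: Isotope, duration_days: float,
                       clamp: bool = True,
                       d_inventory: Literal["carbon", "hydrogen"] = "carbon",
                       consts: IsotopeConstants = DEFAULT_CONSTANTS,
                       ) -> ProductionRate:
    """Label incorporation rate of one lipid, pmol isotope/L/day.

    For isotope "D" the atom inventory multiplied by dF(D) is, by default, the
    carbon produced (``d_inventory="carbon"``, the literal published form of
    the rate formula); ``d_inventory="hydrogen"`` instead scales by the
    hydrogen produced, using the lipid's hydrogen count, which is the
    element-consistent reading. The choice is recorded implicitly in
    ``c_produced`` and should be echoed in output provenance.

    With ``clamp`` (default) negative rates - apparent label loss or net lipid
    loss - are reported as 0 with the ``clamped`` flag set.
    """
    if duration_days <= 0:
        raise PlfaError(f"duration {duration_days} days must be positive")
    produced_c = carbon_produced(t0, tend)
    if isotope == "13C":
        df = excess_atom_fraction(tend.delta_13c, t0.delta_13c, consts)
        produced = produced_c
    else:
        df = excess_atom_fraction(tend.delta_d, t0.delta_d, consts)
        if d_inventory == "hydrogen":
            produced = produced_c / t0.name.n_carbons * t0.name.n_hydrogens
        else:
            produced = produced_c
    rate = df * produced / duration_days
    clamped = False
    if clamp and rate < 0:
        rate, clamped = 0.0, True
    return ProductionRate(name=t0.name, isotope=isotope, rate=rate,
                          c_produced=produced, delta_f=df, clamped=clamped)


def ra_rt(ra: ProductionRate, rt: ProductionRate,
          f13c_dic: AtomFraction | float = 1.0,
          fd_substrate: AtomFraction | float = 1.0,
          heterotrophic_max: float = HETEROTROPHIC_MAX,
          autotrophic_min: float = AUTOTROPHIC_MIN) -> TrophicCall:
    """Trophic classification from the Ra/Rt ratio.

    Ra (13C rate, inorganic carbon assimilation) and Rt (D rate, total lipid
    production) are each divided by the label atom fraction of their source
    pool before the ratio, so that differing label strengths of the DIC and
    substrate pools do not bias the comparison. Pass 1.0 for both pools to
    reproduce the unnormalized, published-form ratio.
    """
    if ra.isotope != "13C" or rt.isotope != "D":
        raise PlfaError("ra must be the 13C rate and rt the D rate")
    f_a = f13c_dic.value if isinstance(f13c_dic, AtomFraction) else f13c_dic
    f_t = fd_substrate.value if isinstance(fd_substrate, AtomFraction) else fd_substrate
    if not 0 < f_a <= 1 or not 0 < f_t <= 1:
        raise PlfaError("source-pool atom fractions must be in (0, 1]")
    ra_norm = ra.rate / f_a
    rt_norm = rt.rate / f_t
    if rt_norm <= 0:
        raise UndefinedRatioError(
            "total production rate Rt is zero; Ra/Rt undefined"
        )
    ratio = ra_norm / rt_norm
    if ratio <= heterotrophic_max:
        call = "heterotrophic"
    elif ratio >= autotrophic_min:
        call = "autotrophic"
    else:
        call = "mixed"
    return TrophicCall(name=ra.name, ra=ra_norm, rt=rt_norm, ra_rt=ratio,
                       call=call)


def acetogen_expectation(fraction_c1: float) -> float:
    """Expected Ra/Rt for an acetogen assimilating a methyl (C1) group.

    Under the two-carbon acetyl-CoA model, each acetyl unit combines one
    methyl-branch carbon with one CO2-derived carbonyl carbon. If a fraction
    ``fraction_c1`` of the acetyl carbon derives from the (heterotrophic)
    methyl group, the expected inorganic-carbon share - and hence Ra/Rt - is
    1 - fraction_c1. Pure Wood-Ljungdahl operation with the methyltransferase
    branch (one carbon each) gives 0.5.
    """
    if not 0 <= fraction_c1 <= 1:
        raise PlfaError(f"fraction_c1 {fraction_c1} outside [0, 1]")
    return 1.0 - fraction_c1
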