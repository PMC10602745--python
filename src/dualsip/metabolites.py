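"""Metabolomic-SIP: dual 13C/D isotopologue matching on HR-MS peak lists.

A 13C substitution adds ~1.00336 Da to a molecular ion and a deuterium
substitution ~1.00628 Da; an orbitrap-class instrument resolves the ~2.9 mDa
difference, so the isotopologue fine structure of an exometabolite reveals how
many atoms of each label it carries. A deuterium count divisible by three is
the signature of an intact trideuterated methyl group (CD3) transferred from
the dimethoxy donor by a methyltransferase pathway, rather than D scrambled
into C-H bonds one at a time.

The module consumes centroided per-feature peak lists (feature finding is
upstream) and produces per-feature label assignments, a census of labeled
species, and substrate-consumption summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

from .isotopes import IsotopeConstants, DEFAULT_CONSTANTS

MAX_K_DEFAULT = 12
MIN_INTENSITY_FRAC_DEFAULT = 0.01


class MetabError(ValueError):
    pass


class MissingBaseError(MetabError):
    pass


class InvalidBaselineError(MetabError):
    pass


@dataclass(frozen=True)
class Peak:
    mz: float  # Da, centroided
    intensity: float
    rt: Optional[float] = None  # seconds

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise MetabError("m/z must be positive")
        if self.intensity < 0:
            raise MetabError("intensity must be >= 0")


@dataclass(frozen=True)
class SeriesMember:
    k13c: int
    kd: int
    peak: Peak
    ppm_error: float


@dataclass(frozen=True)
class IsotopologueSeries:
    base_mz: float
    base_intensity: float
    members: tuple[SeriesMember, ...]
    ambiguous: tuple[Peak, ...] = ()

    @property
    def max_k13c(self) -> int:
        return max((m.k13c for m in self.members), default=0)

    @property
    def max_kd(self) -> int:
        return max((m.kd for m in self.members), default=0)


@dataclass(frozen=True)
class LabelAssignment:
    series: IsotopologueSeries
    labeled_13c: bool
    labeled_d: bool
    cd3_transfer: bool
    n_cd3_groups: int
    feature_id: str = ""


@dataclass(frozen=True)
class ConsumptionResult:
    compound: str
    rel_conc: float  # remaining fraction of the initial amount
    percent_consumed: float


def required_resolving_power(mass: float,
                             consts: IsotopeConstants = DEFAULT_CONSTANTS) -> float:
    """Resolving power m/dm needed to separate a 13C from a D isotopologue.

    dm is the difference between the two single-substitution mass shifts
    (~2.9 mDa); at higher label counts adjacent grid points can be closer, so
    this is the single-substitution requirement.
    """
    if mass <= 0:
        raise MetabError("mass must be positive")
    return mass / (consts.mass_shift_d - consts.mass_shift_13c)


def _grid(max_k: int) -> list[tuple[int, int]]:
    """All (k13c, kd) label combinations with 1 <= k13c + kd <= max_k."""
    return [(i, j) for i, j in itertools.product(range(max_k + 1), repeat=2)
            if 1 <= i + j <= max_k]


def match_series(base: Peak, peaks: Sequence[Peak], max_k: int = MAX_K_DEFAULT,
                 tol_ppm: float = 2.0,
                 consts: IsotopeConstants = DEFAULT_CONSTANTS,
                 ) -> IsotopologueSeries:
    """Match observed peaks to the (k13c, kd) isotopologue grid of a base ion.

    Each candidate grid point sits at ``base + k13c*dm_C + kd*dm_D``. A peak
    within ``tol_ppm`` of exactly one grid point is assigned there; a peak
    within tolerance of two or more grid points is flagged ambiguous and
    excluded (so resolution-limited peaks cannot inflate label counts). When
    several peaks hit the same grid point the one with the smaller ppm error
    wins, ties broken by lower m/z. The base peak itself must be present in
    ``peaks`` (identical m/z and intensity).
    """
    if tol_ppm <= 0:
        raise MetabError("tol_ppm must be positive")
    if max_k < 1:
        raise MetabError("max_k must be >= 1")
    if base not in peaks:
        raise MissingBaseError("base peak not found in the peak list")
    others = [p for p in peaks if p != base]
    candidates = {
        (i, j): base.mz + i * consts.mass_shift_13c + j * consts.mass_shift_d
        for i, j in _grid(max_k)
    }
    assigned: dict[tuple[int, int], SeriesMember] = {}
    ambiguous: list[Peak] = []
    for peak in sorted(others, key=lambda p: p.mz):
        hits = []
        for key, expected in candidates.items():
            ppm = abs(peak.mz - expected) / expected * 1e6
            if ppm <= tol_ppm:
                hits.append((ppm, key))
        if not hits:
            continue
        if len(hits) > 1:
            ambiguous.append(peak)
            continue
        ppm, key = hits[0]
        incumbent = assigned.get(key)
        if incumbent is None or (ppm, peak.mz) < (incumbent.ppm_error,
                                                  incumbent.peak.mz):
            assigned[key] = SeriesMember(key[0], key[1], peak, ppm)
    members = tuple(sorted(assigned.values(), key=lambda m: (m.k13c, m.kd)))
    return IsotopologueSeries(base_mz=base.mz, base_intensity=base.intensity,
                              members=members, ambiguous=tuple(ambiguous))


def assign_labels(series: IsotopologueSeries,
                  min_intensity_frac: float = MIN_INTENSITY_FRAC_DEFAULT,
                  feature_id: str = "") -> LabelAssignment:
    """Label flags and the CD3 methyl-transfer call for one feature.

    A label type counts as detected only if some member carrying that label
    has intensity >= ``min_intensity_frac`` of the base peak. The CD3 call
    requires the maximum deuterium count (over detected members) to be a
    positive multiple of three; the number of transferred CD3 groups is then
    max_kd / 3.
    """
    if not 0 <= min_intensity_frac < 1:
        raise MetabError("min_intensity_frac must be in [0, 1)")
    floor = min_intensity_frac * series.base_intensity
    detected = [m for m in series.members if m.peak.intensity >= floor]
    labeled_13c = any(m.k13c > 0 for m in detected)
    labeled_d = any(m.kd > 0 for m in detected)
    max_kd = max((m.kd for m in detected), default=0)
    cd3 = max_kd > 0 and max_kd % 3 == 0
    return LabelAssignment(
        series=series, labeled_13c=labeled_13c, labeled_d=labeled_d,
        cd3_transfer=cd3, n_cd3_groups=max_kd // 3 if cd3 else 0,
        feature_id=feature_id,
    )


def count_label_census(assignments: Sequence[LabelAssignment]) -> dict[str, int]:
    """Census over features: how many carry 13C, D, and D divisible by three.

    A feature labeled with both isotopes counts once in each of the first two
    tallies. ``n_divisible_by_3`` counts D-labeled features whose maximum
    deuterium count is a multiple of three (the CD3-transfer candidates).
    """
    n_13c = sum(a.labeled_13c for a in assignments)
    n_d = sum(a.labeled_d for a in assignments)
    n_div3 = sum(a.labeled_d and a.cd3_transfer for a in assignments)
    return {"n_13c_species": n_13c, "n_d_species": n_d,
            "n_divisible_by_3": n_div3}


def substrate_consumption(areas_t0: float, areas_tend: float,
                          compound: str = "veratric_acid") -> ConsumptionResult:
    """Fraction of the initial substrate consumed, from peak areas.

    ``rel_conc`` is the remaining fraction (Tend/T0 area); consumption is
    100 * (1 - rel_conc) percent. An apparent increase gives a negative
    consumption (reported as-is).
    """
    if areas_t0 <= 0:
        raise InvalidBaselineError("initial peak area must be positive")
    if areas_tend < 0:
        raise MetabError("final peak area must be >= 0")
    rel = areas_tend / areas_t0
    return ConsumptionResult(compound=compound, rel_conc=rel,
                             percent_consumed=100.0 * (1.0 - rel))
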