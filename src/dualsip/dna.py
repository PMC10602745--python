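"""DNA-SIP gradient analysis: heavy/light partitioning and the RoOR statistic.

A CsCl gradient is fractionated into ~11-12 density fractions per bottle; reads
per taxon per fraction come from amplicon sequencing of each fraction. A taxon
that assimilated the heavy isotope shifts its DNA toward denser fractions. The
ratio of odds ratios (RoOR) compares the taxon's heavy-vs-light read odds in a
labeled bottle against the same odds in the unlabeled control bottle: RoOR > 1
indicates isotope labeling. Calls additionally require a minimum of five reads
for the taxon in the heavy and light pools of both the labeled and control
bottles, and replicate consensus (both duplicates, or two of three replicates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

MIN_READS_DEFAULT = 5
HALDANE_PSEUDOCOUNT = 0.5
DENSITY_THRESHOLD_DEFAULT = 1.715  # g/mL


class DnaSipError(ValueError):
    pass


class DegenerateSplitError(DnaSipError):
    """All fractions fell on one side of the heavy/light split."""


class DivisionDomainError(DnaSipError):
    """Odds ratio undefined: zero cell with zero pseudocount."""


class DesignMismatchError(DnaSipError):
    """Replicate list does not match the declared design."""


@dataclass(frozen=True)
class FractionProfile:
    """One gradient fraction: buoyant density, DNA yield, and taxon reads."""

    fraction_id: int
    density: float  # g/mL
    dna_mass: float  # ng
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not 1.60 <= self.density <= 1.80:
            raise DnaSipError(
                f"density {self.density} g/mL outside the CsCl range [1.60, 1.80]"
            )
        if any(v < 0 for v in self.counts.values()):
            raise DnaSipError("read counts must be non-negative")


Bottle = Sequence[FractionProfile]


@dataclass(frozen=True)
class BottleSet:
    """Labeled replicates plus one control bottle for a single treatment."""

    treatment: Literal["13C-VA", "13CO2+D-VA", "13CO2"]
    well: str
    labeled_replicates: Sequence[Bottle]
    control_bottle: Bottle
    t0_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labeled_replicates) < 1:
            raise DnaSipError("need at least one labeled replicate")
        for bottle in [*self.labeled_replicates, self.control_bottle]:
            if len(bottle) < 2:
                raise DnaSipError("each bottle needs at least two fractions")
            ids = [f.fraction_id for f in bottle]
            if len(set(ids)) != len(ids):
                raise DnaSipError("fraction ids must be unique within a bottle")
            densities = [f.density for f in bottle]
            if max(densities) - min(densities) < 0.01:
                raise DnaSipError("bottle spans a density range < 0.01 g/mL")

    def taxa(self) -> list[str]:
        names: set[str] = set()
        for bottle in [*self.labeled_replicates, self.control_bottle]:
            for frac in bottle:
                names.update(frac.counts)
        return sorted(names)


@dataclass(frozen=True)
class SplitRule:
    """Heavy/light partition rule: density threshold or top-k densest."""

    kind: Literal["density_threshold", "top_k"]
    threshold: float | None = None
    k: int | None = None

    @classmethod
    def density_threshold(cls, t: float = DENSITY_THRESHOLD_DEFAULT) -> "SplitRule":
        return cls("density_threshold", threshold=t)

    @classmethod
    def top_k(cls, k: int) -> "SplitRule":
        return cls("top_k", k=k)

    def describe(self) -> str:
        if self.kind == "density_threshold":
            return f"density_threshold({self.threshold})"
        return f"top_k({self.k})"


@dataclass(frozen=True)
class HeavyLightSplit:
    heavy_fraction_ids: frozenset[int]
    light_fraction_ids: frozenset[int]
    rule: str

    def __post_init__(self) -> None:
        if self.heavy_fraction_ids & self.light_fraction_ids:
            raise DnaSipError("heavy and light fraction sets overlap")
        if not self.heavy_fraction_ids or not self.light_fraction_ids:
            raise DegenerateSplitError("one side of the split is empty")


@dataclass(frozen=True)
class RoorResult:
    taxon: str
    or_labeled: float
    or_control: float
    roor: float
    passes_read_filter: bool
    called_labeled: bool


def split_heavy_light(bottle: Bottle, rule: SplitRule) -> HeavyLightSplit:
    """Assign every fraction of a bottle to the heavy or light side.

    ``density_threshold(t)`` puts fractions with density > t on the heavy side;
    ``top_k(k)`` takes the k densest. Raises :class:`DegenerateSplitError` when
    either side would be empty (e.g. uniform densities or an extreme threshold).
    """
    ordered = sorted(bottle, key=lambda f: f.density)
    densities = [f.density for f in ordered]
    if len(set(densities)) != len(densities):
        raise DegenerateSplitError("fraction densities are not strictly ordered")
    if rule.kind == "density_threshold":
        if rule.threshold is None:
            raise DnaSipError("density_threshold rule needs a threshold")
        heavy = [f.fraction_id for f in ordered if f.density > rule.threshold]
        light = [f.fraction_id for f in ordered if f.density <= rule.threshold]
    elif rule.kind == "top_k":
        if rule.k is None or rule.k < 1:
            raise DnaSipError("top_k rule needs k >= 1")
        heavy = [f.fraction_id for f in ordered[-rule.k:]]
        light = [f.fraction_id for f in ordered[:-rule.k]]
    else:  # pragma: no cover - dataclass literal guards this
        raise DnaSipError(f"unknown split rule {rule.kind}")
    return HeavyLightSplit(frozenset(heavy), frozenset(light), rule.describe())


def _pool_counts(taxon: str, bottle: Bottle,
                 ids: frozenset[int]) -> tuple[int, int]:
    """(taxon reads, all-other reads) summed over the given fractions."""
    taxon_reads = 0
    other_reads = 0
    for frac in bottle:
        if frac.fraction_id not in ids:
            continue
        for name, reads in frac.counts.items():
            if name == taxon:
                taxon_reads += reads
            else:
                other_reads += reads
    return taxon_reads, other_reads


def odds_ratio_2x2(a: float, b: float, c: float, d: float,
                   pseudocount: float = HALDANE_PSEUDOCOUNT) -> float:
    """OR of the 2x2 table ((a, b), (c, d)) = (a/b) / (c/d).

    The pseudocount is added to every cell only when some cell is zero
    (Haldane-Anscombe correction); exact tables stay exact. A zero cell with
    pseudocount 0 raises :class:`DivisionDomainError`.
    """
    if pseudocount < 0:
        raise DnaSipError("pseudocount must be >= 0")
    cells = (a, b, c, d)
    if any(x == 0 for x in cells):
        if pseudocount == 0:
            raise DivisionDomainError("zero cell with zero pseudocount")
        a, b, c, d = (x + pseudocount for x in cells)
    return (a / b) / (c / d)


def taxon_odds(taxon: str, split: HeavyLightSplit, bottle: Bottle,
               pseudocount: float = HALDANE_PSEUDOCOUNT) -> float:
    """Heavy-vs-light odds ratio for one taxon in one bottle.

    Counts are pooled across each side's fractions before forming the table:
    a = taxon reads in heavy, b = all other reads in heavy, c = taxon reads in
    light, d = all other reads in light.
    """
    a, b = _pool_counts(taxon, bottle, split.heavy_fraction_ids)
    c, d = _pool_counts(taxon, bottle, split.light_fraction_ids)
    return odds_ratio_2x2(a, b, c, d, pseudocount)


def _passes_read_filter(taxon: str, split_l: HeavyLightSplit, labeled: Bottle,
                        split_c: HeavyLightSplit, control: Bottle,
                        min_reads: int) -> bool:
    # strictest reading: the taxon needs >= min_reads in heavy AND light pools
    # of BOTH the labeled and the control bottle
    pools = [
        _pool_counts(taxon, labeled, split_l.heavy_fraction_ids)[0],
        _pool_counts(taxon, labeled, split_l.light_fraction_ids)[0],
        _pool_counts(taxon, control, split_c.heavy_fraction_ids)[0],
        _pool_counts(taxon, control, split_c.light_fraction_ids)[0],
    ]
    return all(p >= min_reads for p in pools)


def roor(taxon: str, labeled_bottle: Bottle, control_bottle: Bottle,
         split_rule: SplitRule = SplitRule.density_threshold(),
         pseudocount: float = HALDANE_PSEUDOCOUNT,
         min_reads: int = MIN_READS_DEFAULT) -> RoorResult:
    """Ratio of odds ratios for one taxon: OR(labeled) / OR(control).

    ``called_labeled`` requires RoOR > 1 and the minimum-read filter.
    """
    present = any(taxon in f.counts and f.counts[taxon] > 0
                  for f in [*labeled_bottle, *control_bottle])
    if not present:
        raise DnaSipError(f"taxon {taxon!r} absent from both bottles")
    split_l = split_heavy_light(labeled_bottle, split_rule)
    split_c = split_heavy_light(control_bottle, split_rule)
    or_l = taxon_odds(taxon, split_l, labeled_bottle, pseudocount)
    or_c = taxon_odds(taxon, split_c, control_bottle, pseudocount)
    value = or_l / or_c
    passes = _passes_read_filter(taxon, split_l, labeled_bottle,
                                 split_c, control_bottle, min_reads)
    return RoorResult(
        taxon=taxon, or_labeled=or_l, or_control=or_c, roor=value,
        passes_read_filter=passes,
        called_labeled=bool(value > 1.0 and passes),
    )


def consensus_call(per_replicate: Sequence[RoorResult],
                   design: Literal["duplicates", "triplicates"]) -> bool:
    """Replicate-consensus labeling call.

    Duplicates (single-label incubations) require the taxon called in both
    bottles; triplicates (dual-label incubations) require two of three.
    """
    expected = {"duplicates": 2, "triplicates": 3}[design]
    if len(per_replicate) != expected:
        raise DesignMismatchError(
            f"{design} design expects {expected} replicates, got {len(per_replicate)}"
        )
    n_called = sum(r.called_labeled for r in per_replicate)
    return n_called == 2 if design == "duplicates" else n_called >= 2


def analyze_bottle_set(bottles: BottleSet,
                       split_rule: SplitRule = SplitRule.density_threshold(),
                       pseudocount: float = HALDANE_PSEUDOCOUNT,
                       min_reads: int = MIN_READS_DEFAULT) -> pd.DataFrame:
    """Per-taxon, per-replicate RoOR table with the consensus call.

    Returns a DataFrame with one row per (taxon, replicate) and a
    ``consensus_labeled`` column repeated per taxon.
    """
    design: Literal["duplicates", "triplicates"]
    design = "duplicates" if len(bottles.labeled_replicates) == 2 else "triplicates"
    rows = []
    for taxon in bottles.taxa():
        results = []
        for i, rep in enumerate(bottles.labeled_replicates, start=1):
            try:
                res = roor(taxon, rep, bottles.control_bottle,
                           split_rule, pseudocount, min_reads)
            except DnaSipError:
                res = RoorResult(taxon, math.nan, math.nan, math.nan, False, False)
            results.append((i, res))
        if len(results) in (2, 3):
            consensus = consensus_call([r for _, r in results], design)
        else:
            consensus = all(r.called_labeled for _, r in results)
        for i, res in results:
            rows.append({
                "taxon": taxon, "replicate": i,
                "or_labeled": res.or_labeled, "or_control": res.or_control,
                "roor": res.roor,
                "passes_read_filter": res.passes_read_filter,
                "called_labeled": res.called_labeled,
                "consensus_labeled": consensus,
            })
    return pd.DataFrame(rows)


def labeled_community_table(results: Iterable[RoorResult],
                            heavy_counts: Mapping[str, int],
                            min_rel_abundance: float = 0.01) -> pd.DataFrame:
    """Relative abundance of consensus-labeled taxa among heavy-fraction reads.

    Taxa below ``min_rel_abundance`` are folded into an ``"other"`` row so the
    shown abundances still sum to 1. Returns an empty table (with columns) when
    nothing is labeled.
    """
    if not 0 <= min_rel_abundance < 1:
        raise DnaSipError("min_rel_abundance must be in [0, 1)")
    labeled = [r.taxon for r in results if r.called_labeled]
    total = sum(heavy_counts.get(t, 0) for t in labeled)
    if not labeled or total == 0:
        return pd.DataFrame(columns=["taxon", "rel_abundance"])
    rows = []
    other = 0.0
    for taxon in sorted(labeled):
        rel = heavy_counts.get(taxon, 0) / total
        if rel > min_rel_abundance:
            rows.append({"taxon": taxon, "rel_abundance": rel})
        else:
            other += rel
    if other > 0:
        rows.append({"taxon": "other", "rel_abundance": other})
    return pd.DataFrame(rows)
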