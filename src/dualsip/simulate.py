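"""Synthetic-data generators with known ground truth for all three SIP stages.

Each generator is a pure function of (specification, seed) and emulates the
statistical structure the corresponding analysis assumes:

* gradients - per-taxon buoyant density from GC content, a density shift
  proportional to the labeled atom fraction, Gaussian band spreading across
  fractions, and multinomial read sampling;
* PLFA tables - lipid pools growing by producer-specific rates, with end-point
  isotope deltas back-computed from carbon/hydrogen mass balance so the
  incorporation-rate formula recovers the configured rates exactly at zero
  noise;
* peak lists - isotopologue ladders at the exact 13C and D mass shifts with
  ppm-scale m/z jitter.

The ground truth (who is labeled and by how much) is returned alongside every
table so recovery tests never depend on external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .dna import BottleSet, FractionProfile
from .isotopes import (
    DEFAULT_CONSTANTS,
    IsotopeConstants,
    delta13c,
    delta_d,
    delta_to_atom_fraction,
    atom_fraction_to_ratio,
    ratio_to_delta,
    AtomFraction,
)
from .plfa import parse_plfa_name

# Buoyant-density model constants (standard CsCl SIP literature values):
# unlabeled DNA density rho = 1.66 + 0.098 * GC; a fully 13C-labeled genome
# shifts by ~0.036 g/mL; gradient bands spread with sd sigma_rho.
RHO_INTERCEPT = 1.66
RHO_GC_SLOPE = 0.098
FULL_LABEL_SHIFT = 0.036
SIGMA_RHO_DEFAULT = 0.006

BASELINE_DELTA_13C = -28.0   # permil, typical organic biomass
BASELINE_DELTA_D = -150.0    # permil, typical lipid hydrogen


@dataclass(frozen=True)
class TaxonSpec:
    """One community member and its labeling truth.

    ``label_atom_fraction`` is the heavy-isotope atom fraction of the taxon's
    newly synthesized DNA (it sets the density shift); ``turnover`` is the
    fraction of the taxon's DNA pool that was newly synthesized during the
    incubation, so a labeled taxon bands as a mixture of an unshifted (old
    DNA) and a shifted (new DNA) component. ``turnover = 1`` reproduces a
    single fully shifted band.
    """

    name: str
    relative_abundance: float
    gc_content: float
    label_atom_fraction: float = 0.0
    turnover: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0 <= self.label_atom_fraction <= 1:
            raise ValueError("label_atom_fraction must be in [0, 1]")
        if not 0 <= self.turnover <= 1:
            raise ValueError("turnover must be in [0, 1]")


@dataclass(frozen=True)
class CommunitySpec:
    """Design of a synthetic gradient experiment."""

    taxa: Sequence[TaxonSpec]
    read_depth: int = 2000
    n_fractions: int = 12
    density_grid: Optional[Sequence[float]] = None
    n_labeled_replicates: int = 2
    sigma_rho: float = SIGMA_RHO_DEFAULT
    total_dna_ng: float = 50.0

    def __post_init__(self) -> None:
        total = sum(t.relative_abundance for t in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon abundances sum to {total}, not 1")
        if self.n_fractions < 2:
            raise ValueError("need at least two fractions")
        if self.density_grid is not None and len(set(self.density_grid)) < 2:
            raise ValueError("density grid is degenerate (single density)")

    def grid(self) -> np.ndarray:
        if self.density_grid is not None:
            return np.asarray(self.density_grid, dtype=float)
        return np.round(np.linspace(1.685, 1.755, self.n_fractions), 4)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset, reproducible from (spec, seed)."""

    stage: str  # dna | plfa | metab
    seed: int
    records: tuple = ()
    params: Mapping[str, object] = field(default_factory=dict)


def _bottle(spec: CommunitySpec, labeled: bool,
            rng: np.random.Generator) -> list[FractionProfile]:
    grid = spec.grid()
    abund = np.array([t.relative_abundance for t in spec.taxa])

    def band(center: float) -> np.ndarray:
        z = (grid - center) / spec.sigma_rho
        w = np.exp(-0.5 * z ** 2)
        return w / w.sum()

    # each taxon's DNA bands as a mixture of old (unshifted) and, in labeled
    # bottles, newly synthesized (density-shifted) components
    weights = np.empty((len(spec.taxa), len(grid)))
    for i, t in enumerate(spec.taxa):
        rho0 = RHO_INTERCEPT + RHO_GC_SLOPE * t.gc_content
        if labeled and t.label_atom_fraction > 0 and t.turnover > 0:
            shifted = band(rho0 + FULL_LABEL_SHIFT * t.label_atom_fraction)
            weights[i] = (1 - t.turnover) * band(rho0) + t.turnover * shifted
        else:
            weights[i] = band(rho0)
    probs = (abund[:, None] * weights).ravel()
    probs /= probs.sum()
    reads = rng.multinomial(spec.read_depth, probs).reshape(len(spec.taxa),
                                                            len(grid))
    dna_per_fraction = (abund[:, None] * weights).sum(axis=0)
    dna_per_fraction = dna_per_fraction / dna_per_fraction.sum() * spec.total_dna_ng
    fractions = []
    for j, density in enumerate(grid):
        counts = {t.name: int(reads[i, j]) for i, t in enumerate(spec.taxa)
                  if reads[i, j] > 0}
        fractions.append(FractionProfile(
            fraction_id=j + 1, density=float(density),
            dna_mass=float(dna_per_fraction[j]), counts=counts,
        ))
    return fractions


def generate_gradient(spec: CommunitySpec, seed: int,
                      treatment: str = "13C-VA",
                      well: str = "H41") -> tuple[BottleSet, SyntheticTruth]:
    """Simulate a labeled/control gradient experiment with known truth.

    Labeled replicates place each taxon at its shifted buoyant density; the
    control bottle uses the unshifted densities (label atom fraction 0).
    """
    rng = np.random.default_rng(seed)
    labeled_reps = [_bottle(spec, labeled=True, rng=rng)
                    for _ in range(spec.n_labeled_replicates)]
    control = _bottle(spec, labeled=False, rng=rng)
    t0 = {t.name: int(round(t.relative_abundance * spec.read_depth))
          for t in spec.taxa}
    bottles = BottleSet(treatment=treatment, well=well,  # type: ignore[arg-type]
                        labeled_replicates=labeled_reps,
                        control_bottle=control, t0_counts=t0)
    truth = SyntheticTruth(
        stage="dna", seed=seed,
        records=tuple((t.name, t.label_atom_fraction) for t in spec.taxa
                      if t.label_atom_fraction > 0),
        params={"read_depth": spec.read_depth, "sigma_rho": spec.sigma_rho,
                "n_fractions": spec.n_fractions,
                "full_label_shift": FULL_LABEL_SHIFT},
    )
    return bottles, truth


@dataclass(frozen=True)
class LipidProducer:
    """One (possibly composite) lipid producer population.

    ``profile`` distributes the producer's carbon production over lipids
    (weights are normalized); ``growth`` is total lipid carbon production in
    pmol C/L/day; ``dic_fraction`` is the fraction of that new carbon fixed
    from the dissolved-inorganic-carbon pool (0 = pure heterotroph, 1 = pure
    autotroph). All new lipid hydrogen is assumed to carry the substrate
    deuterium pool's excess, which makes the D rate a tracer of total
    production.
    """

    profile: Mapping[str, float]
    growth: float  # pmol C / L / day
    dic_fraction: float

    def __post_init__(self) -> None:
        if self.growth < 0:
            raise ValueError("growth must be >= 0")
        if not 0 <= self.dic_fraction <= 1:
            raise ValueError("dic_fraction must be in [0, 1]")


@dataclass(frozen=True)
class LabelPools:
    """Excess atom fractions of the two label source pools."""

    f13c_dic: float = 0.9      # 99 atom% bicarbonate diluted by ambient DIC
    fd_substrate: float = 0.6  # six of ten VA hydrogens sit in the CD3 groups

    def __post_init__(self) -> None:
        if not 0 < self.f13c_dic <= 1 or not 0 < self.fd_substrate <= 1:
            raise ValueError("pool atom fractions must be in (0, 1]")


def generate_plfa(producers: Sequence[LipidProducer],
                  pools: LabelPools = LabelPools(),
                  duration_days: float = 84.0,
                  noise_sd_delta: float = 0.0,
                  seed: int = 0,
                  t0_concentration: float = 50.0,
                  well: str = "H41", treatment: str = "13CO2+D-VA",
                  consts: IsotopeConstants = DEFAULT_CONSTANTS,
                  ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate dual-label PLFA T0/Tend measurement tables.

    End-point deltas follow carbon/hydrogen mass balance between the old lipid
    pool (baseline composition) and newly produced lipid whose carbon carries
    ``dic_fraction * f13c_dic`` excess 13C and whose hydrogen carries
    ``fd_substrate`` excess D. The truth records hold, per lipid, the rates the
    incorporation-rate formula measures on noise-free data, so a zero-noise
    round trip is exact. Gaussian noise of sd ``noise_sd_delta`` (permil) is
    added to every reported delta.
    """
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)

    lipids: dict[str, dict[str, float]] = {}
    for prod in producers:
        wsum = sum(prod.profile.values())
        for name, w in prod.profile.items():
            rec = lipids.setdefault(name, {"growth": 0.0, "dic_growth": 0.0})
            g = prod.growth * w / wsum
            rec["growth"] += g
            rec["dic_growth"] += g * prod.dic_fraction

    f13_base = delta_to_atom_fraction(delta13c(BASELINE_DELTA_13C), consts).value
    fd_base = delta_to_atom_fraction(delta_d(BASELINE_DELTA_D), consts).value

    rows = []
    truth_records = []
    for raw_name in sorted(lipids):
        rec = lipids[raw_name]
        name = parse_plfa_name(raw_name)
        growth = rec["growth"]
        a = rec["dic_growth"] / growth if growth > 0 else 0.0

        conc_t0 = t0_concentration
        new_c = growth * duration_days                   # pmol C/L
        conc_tend = conc_t0 + new_c / name.n_carbons
        old_c = conc_t0 * name.n_carbons
        dilution = new_c / (old_c + new_c) if new_c > 0 else 0.0

        # pool atom fractions at Tend by mass balance (H dilutes identically)
        f13_tend = f13_base + dilution * a * pools.f13c_dic
        fd_tend = fd_base + dilution * pools.fd_substrate

        d13_t0, dd_t0 = BASELINE_DELTA_13C, BASELINE_DELTA_D
        d13_tend = ratio_to_delta(
            atom_fraction_to_ratio(AtomFraction(f13_tend, "C")), "C", consts).value
        dd_tend = ratio_to_delta(
            atom_fraction_to_ratio(AtomFraction(fd_tend, "H")), "H", consts).value

        # what the incorporation-rate formula measures on noise-free data
        rate_13c = (f13_tend - f13_base) * new_c / duration_days
        rate_d = (fd_tend - fd_base) * new_c / duration_days
        truth_records.append((raw_name, growth, a, rate_13c, rate_d))

        for tp, conc, d13, dd in (("T0", conc_t0, d13_t0, dd_t0),
                                  ("Tend", conc_tend, d13_tend, dd_tend)):
            rows.append({
                "well": well, "treatment": treatment, "timepoint": tp,
                "plfa_name": raw_name, "conc_pmol_per_l": conc,
                "delta13c_permil": d13 + rng.normal(0.0, noise_sd_delta)
                if noise_sd_delta > 0 else d13,
                "deltad_permil": dd + rng.normal(0.0, noise_sd_delta)
                if noise_sd_delta > 0 else dd,
            })
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        stage="plfa", seed=seed, records=tuple(truth_records),
        params={"duration_days": duration_days, "f13c_dic": pools.f13c_dic,
                "fd_substrate": pools.fd_substrate,
                "noise_sd_delta": noise_sd_delta,
                "t0_concentration": t0_concentration},
    )
    return table, truth


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic MS feature and its true label content."""

    feature_id: str
    base_mz: float
    k13c: int = 0
    kd: int = 0
    base_intensity: float = 1e6
    decay: float = 0.6  # intensity ratio between successive isotopologues

    def __post_init__(self) -> None:
        if self.base_mz <= 0:
            raise ValueError("base m/z must be positive")
        if self.k13c < 0 or self.kd < 0:
            raise ValueError("label counts must be >= 0")


def generate_peaklists(features: Sequence[FeatureSpec], ppm_noise: float = 0.0,
                       seed: int = 0,
                       consts: IsotopeConstants = DEFAULT_CONSTANTS,
                       ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate centroided isotopologue peak lists with known label counts.

    Each feature emits its base peak plus a 13C ladder up to ``k13c`` and a D
    ladder up to ``kd``, at the exact substitution mass shifts, with relative
    m/z jitter drawn from Normal(0, ppm_noise) ppm.
    """
    if ppm_noise < 0:
        raise ValueError("ppm_noise must be >= 0")
    rng = np.random.default_rng(seed)

    def jitter(mz: float) -> float:
        if ppm_noise == 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, ppm_noise) * 1e-6)

    rows = []
    for feat in features:
        rows.append({"feature_id": feat.feature_id, "mz": jitter(feat.base_mz),
                     "intensity": feat.base_intensity, "rt": np.nan,
                     "role": "base"})
        for k in range(1, feat.k13c + 1):
            rows.append({
                "feature_id": feat.feature_id,
                "mz": jitter(feat.base_mz + k * consts.mass_shift_13c),
                "intensity": feat.base_intensity * feat.decay ** k,
                "rt": np.nan, "role": "13c",
            })
        for k in range(1, feat.kd + 1):
            rows.append({
                "feature_id": feat.feature_id,
                "mz": jitter(feat.base_mz + k * consts.mass_shift_d),
                "intensity": feat.base_intensity * feat.decay ** k,
                "rt": np.nan, "role": "d",
            })
    table = pd.DataFrame(rows)
    truth = SyntheticTruth(
        stage="metab", seed=seed,
        records=tuple((f.feature_id, f.k13c, f.kd) for f in features),
        params={"ppm_noise": ppm_noise},
    )
    return table, truth


def null_community_spec(n_taxa: int = 100, alpha: float = 0.15,
                        seed: int = 0, read_depth: int = 2000,
                        n_labeled_replicates: int = 2,
                        labeled: Sequence[TaxonSpec] = ()) -> CommunitySpec:
    """A realistic unlabeled background community for gradient simulations.

    Groundwater amplicon tables at genus level are strongly uneven - a few
    dominant genera over a long tail of rare ones - which is emulated with
    symmetric-Dirichlet(alpha) relative abundances over ``n_taxa`` taxa and
    GC contents ~ Normal(0.50, 0.06) clipped to [0.30, 0.70]. Optional
    ``labeled`` taxa are prepended and the background rescaled to fill the
    remaining abundance.
    """
    rng = np.random.default_rng(seed)
    abund = rng.dirichlet(np.full(n_taxa, alpha))
    gc = np.clip(rng.normal(0.50, 0.06, n_taxa), 0.30, 0.70)
    reserved = sum(t.relative_abundance for t in labeled)
    if reserved >= 1:
        raise ValueError("labeled taxa already occupy the whole community")
    scale = (1.0 - reserved) / abund.sum()
    taxa = list(labeled) + [
        TaxonSpec(f"taxon_{i:03d}", float(a * scale), float(g))
        for i, (a, g) in enumerate(zip(abund, gc))
    ]
    return CommunitySpec(taxa=taxa, read_depth=read_depth,
                         n_labeled_replicates=n_labeled_replicates)


def spiked_community_spec(label_abundance: float = 0.05,
                          label_atom_fraction: float = 1.0,
                          turnover: float = 0.5, gc: float = 0.50,
                          **kwargs) -> CommunitySpec:
    """Background community plus one labeled taxon named ``"labeled"``."""
    spike = TaxonSpec("labeled", label_abundance, gc,
                      label_atom_fraction, turnover)
    return null_community_spec(labeled=(spike,), **kwargs)


# ---------------------------------------------------------------------------
# Scenario presets named after the sampled wells. Treatments, replicate
# designs and durations follow the incubation setup (duplicates for single
# labels, triplicates for the dual label; 12 weeks for the H4 site, 5 weeks
# for H5). Community compositions are invented fixtures using taxa reported
# as dominant in each well.


def _community(taxa: Sequence[tuple[str, float, float, float]],
               n_reps: int) -> CommunitySpec:
    return CommunitySpec(
        taxa=[TaxonSpec(*t) for t in taxa],
        n_labeled_replicates=n_reps,
    )


SCENARIOS: dict[str, dict[str, object]] = {
    "h41-va": {
        "treatment": "13C-VA", "well": "H41", "design": "duplicates",
        "duration_days": 84.0,
        "community": _community([
            ("Hyphomicrobium", 0.10, 0.62, 1.0),
            ("Sphingobium", 0.08, 0.63, 1.0),
            ("Microbacteriaceae", 0.12, 0.68, 0.6),
            ("Nitrospira", 0.20, 0.55, 0.0),
            ("Caulobacteraceae", 0.25, 0.64, 0.0),
            ("Chloroflexi", 0.25, 0.57, 0.0),
        ], n_reps=2),
        "producers": [
            LipidProducer({"18:1w7": 0.7, "16:0": 0.3}, growth=30.0,
                          dic_fraction=0.15),
            LipidProducer({"a15:0": 0.5, "a17:0": 0.5}, growth=10.0,
                          dic_fraction=0.1),
        ],
    },
    "h43-dual": {
        "treatment": "13CO2+D-VA", "well": "H43", "design": "triplicates",
        "duration_days": 84.0,
        "community": _community([
            ("Acetobacterium", 0.15, 0.44, 1.0),
            ("Ferribacterium", 0.10, 0.60, 0.3),
            ("Curvibacter", 0.10, 0.61, 0.0),
            ("Desulfosporosinus", 0.15, 0.42, 0.0),
            ("Pelosinus", 0.20, 0.40, 0.0),
            ("Thermodesulfovibrionia", 0.30, 0.50, 0.0),
        ], n_reps=3),
        "producers": [
            # acetogen: ~half of acetyl carbon from CO2, half from the methyl
            LipidProducer({"16:0": 0.4, "16:1w7": 0.3, "18:1w7": 0.3},
                          growth=25.0, dic_fraction=0.45),
        ],
    },
    "h51-dual": {
        "treatment": "13CO2+D-VA", "well": "H51", "design": "triplicates",
        "duration_days": 35.0,
        "community": _community([
            ("Hyphomicrobium", 0.08, 0.62, 1.0),
            ("Microbacterium", 0.10, 0.69, 0.8),
            ("Vicinamibacteraceae", 0.12, 0.66, 0.5),
            ("Nitrospira", 0.30, 0.55, 0.0),
            ("Chloroflexi", 0.40, 0.57, 0.0),
        ], n_reps=3),
        "producers": [
            LipidProducer({"18:1w7": 0.6, "a15:0": 0.2, "a17:0": 0.2},
                          growth=40.0, dic_fraction=0.2),
        ],
    },
    "h52-co2": {
        "treatment": "13CO2", "well": "H52", "design": "duplicates",
        "duration_days": 35.0,
        "community": _community([
            ("Sulfuritalea", 0.10, 0.60, 0.7),
            ("Ahniella", 0.08, 0.65, 0.5),
            ("Gallionellaceae", 0.22, 0.52, 0.0),
            ("Omnitrophales", 0.30, 0.45, 0.0),
            ("Brocadiales", 0.30, 0.40, 0.0),
        ], n_reps=2),
        "producers": [
            LipidProducer({"10Me16:0": 0.5, "16:1w7": 0.3, "18:1w7": 0.2},
                          growth=8.0, dic_fraction=0.6),
        ],
    },
}


def scenario_preset(name: str) -> dict[str, object]:
    """Return the (community, producers, design) preset for a named scenario."""
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
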