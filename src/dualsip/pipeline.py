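"""End-to-end orchestration of the three SIP analysis stages.

A run is driven by a :class:`RunConfig` (loadable from YAML). Every stage
writes its tables with a provenance header, and the run as a whole writes a
machine-readable manifest (parameters, seeds, input checksums, outputs) so a
rerun with the same config reproduces the same files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .dna import SplitRule, analyze_bottle_set, labeled_community_table, RoorResult
from .io import (
    bottleset_to_frame,
    frame_to_bottleset,
    frame_to_plfa_pairs,
    read_table,
    sha256_of,
    write_table,
)
from .metabolites import (
    Peak,
    assign_labels,
    count_label_census,
    match_series,
    substrate_consumption,
)
from .plfa import incorporation_rate, ra_rt, UndefinedRatioError
from .simulate import (
    FeatureSpec,
    LabelPools,
    generate_gradient,
    generate_peaklists,
    generate_plfa,
    scenario_preset,
)


class ConfigError(ValueError):
    """Invalid run configuration; message carries the offending field path."""


class DataError(ValueError):
    """Invalid or missing stage input data."""


@dataclass
class DnaParams:
    input: Optional[str] = None
    split_rule: str = "density_threshold"
    density_threshold: float = 1.715
    top_k: int = 3
    pseudocount: float = 0.5
    min_reads: int = 5
    min_rel_abundance: float = 0.01

    def rule(self) -> SplitRule:
        if self.split_rule == "density_threshold":
            return SplitRule.density_threshold(self.density_threshold)
        if self.split_rule == "top_k":
            return SplitRule.top_k(self.top_k)
        raise ConfigError(f"dna.split_rule: unknown rule {self.split_rule!r}")


@dataclass
class PlfaParams:
    input: Optional[str] = None
    duration_days: float = 84.0
    f13c_dic: float = 0.9
    fd_substrate: float = 0.6
    d_inventory: str = "carbon"  # or "hydrogen"
    clamp_negative: bool = True
    heterotrophic_max: float = 0.3
    autotrophic_min: float = 0.8


@dataclass
class MetabParams:
    input: Optional[str] = None
    tol_ppm: float = 2.0
    max_k: int = 12
    min_intensity_frac: float = 0.01
    # compound -> [area_t0, area_tend]
    consumption_areas: Mapping[str, Sequence[float]] = field(default_factory=dict)


@dataclass
class RunConfig:
    outdir: str = "results"
    seed: int = 1
    scenario: Optional[str] = None  # synthetic preset when no inputs given
    stages: Sequence[str] = ("dna", "plfa", "metab")
    dna: DnaParams = field(default_factory=DnaParams)
    plfa: PlfaParams = field(default_factory=PlfaParams)
    metab: MetabParams = field(default_factory=MetabParams)

    @classmethod
    def from_dict(cls, raw: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        kwargs: dict = dict(raw)
        for name, sub in (("dna", DnaParams), ("plfa", PlfaParams),
                          ("metab", MetabParams)):
            if name in kwargs:
                block = kwargs[name]
                if not isinstance(block, Mapping):
                    raise ConfigError(f"{name}: expected a mapping")
                sub_known = {f.name for f in dataclasses.fields(sub)}
                sub_unknown = set(block) - sub_known
                if sub_unknown:
                    raise ConfigError(
                        f"{name}.{sorted(sub_unknown)[0]}: unknown field")
                kwargs[name] = sub(**block)
        cfg = cls(**kwargs)
        bad = set(cfg.stages) - {"dna", "plfa", "metab"}
        if bad:
            raise ConfigError(f"stages: unknown stage {sorted(bad)[0]!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _default_features(scenario: str) -> list[FeatureSpec]:
    """Synthetic exometabolite features for a scenario preset.

    The dual-label H4 scenarios include CD3-bearing features (deuterium counts
    in multiples of three) plus 13C-labeled and unlabeled features; the 5-week
    H5 scenarios produce no labeled exometabolites.
    """
    if scenario == "h41-va":
        feats = [FeatureSpec("va", 182.05791, k13c=0, kd=0)]
        for i in range(2):
            feats.append(FeatureSpec(f"c13_{i}", 150.0 + 7.1 * i,
                                     k13c=1 + i, kd=0))
        for i in range(4):  # every D count a multiple of three
            feats.append(FeatureSpec(f"cd3_{i}", 210.0 + 9.3 * i,
                                     k13c=0, kd=3 * (1 + i % 2)))
        return feats
    if scenario == "h43-dual":
        feats = [FeatureSpec("va", 182.05791, k13c=0, kd=0)]
        for i in range(3):
            feats.append(FeatureSpec(f"c13_{i}", 150.0 + 7.1 * i,
                                     k13c=1 + i, kd=0))
        for i, kd in enumerate((3, 6, 2, 4)):  # half CD3-compatible
            feats.append(FeatureSpec(f"d_{i}", 210.0 + 9.3 * i,
                                     k13c=0, kd=kd))
        return feats
    return [FeatureSpec("va", 182.05791, k13c=0, kd=0),
            FeatureSpec("u0", 168.042, k13c=0, kd=0),
            FeatureSpec("u1", 196.037, k13c=0, kd=0)]


def simulate_inputs(config: RunConfig, outdir: Path) -> dict[str, Path]:
    """Generate synthetic stage inputs for the configured scenario preset."""
    if config.scenario is None:
        raise ConfigError("scenario: required when no stage inputs are given")
    preset = scenario_preset(config.scenario)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    truth_blob: dict[str, object] = {}

    bottles, dna_truth = generate_gradient(
        preset["community"], seed=config.seed,
        treatment=preset["treatment"], well=preset["well"])
    paths["dna"] = write_table(
        bottleset_to_frame(bottles), outdir / "gradient.tsv",
        {"scenario": config.scenario, "seed": config.seed})
    truth_blob["dna"] = {"labeled_taxa": dict(dna_truth.records),
                         "params": dict(dna_truth.params)}

    plfa_table, plfa_truth = generate_plfa(
        preset["producers"],
        pools=LabelPools(config.plfa.f13c_dic, config.plfa.fd_substrate),
        duration_days=preset["duration_days"], noise_sd_delta=2.0,
        seed=config.seed, well=preset["well"], treatment=preset["treatment"])
    paths["plfa"] = write_table(
        plfa_table, outdir / "plfa.csv",
        {"scenario": config.scenario, "seed": config.seed,
         "duration_days": preset["duration_days"]})
    truth_blob["plfa"] = {
        "rates": [
            {"plfa_name": name, "growth_pmol_c_l_day": g, "dic_fraction": a,
             "rate_13c": r13, "rate_d": rd}
            for name, g, a, r13, rd in plfa_truth.records
        ],
        "params": dict(plfa_truth.params),
    }

    peaks, metab_truth = generate_peaklists(
        _default_features(config.scenario), ppm_noise=0.5, seed=config.seed)
    paths["metab"] = write_table(
        peaks, outdir / "peaks.csv",
        {"scenario": config.scenario, "seed": config.seed, "ppm_noise": 0.5})
    truth_blob["metab"] = {
        "features": [{"feature_id": f, "k13c": k13, "kd": kd}
                     for f, k13, kd in metab_truth.records]}

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth_blob, indent=2))
    paths["truth"] = truth_path
    return paths


def run_dna_stage(config: RunConfig, outdir: Path) -> dict[str, Path]:
    if config.dna.input is None:
        raise DataError("dna stage requested but no input table configured")
    df = read_table(config.dna.input)
    bottles = frame_to_bottleset(df)
    rule = config.dna.rule()
    table = analyze_bottle_set(bottles, rule, config.dna.pseudocount,
                               config.dna.min_reads)
    prov = {"split_rule": rule.describe(), "pseudocount": config.dna.pseudocount,
            "min_reads": config.dna.min_reads, "seed": config.seed}
    out = {"roor": write_table(table, outdir / "roor.tsv", prov)}

    consensus = (table.groupby("taxon")["consensus_labeled"].first()
                 .reset_index())
    out["consensus"] = write_table(consensus, outdir / "consensus.tsv", prov)

    # heavy-fraction reads pooled over labeled replicates, for abundance
    heavy: dict[str, int] = {}
    for rep in bottles.labeled_replicates:
        from .dna import split_heavy_light
        split = split_heavy_light(rep, rule)
        for frac in rep:
            if frac.fraction_id in split.heavy_fraction_ids:
                for taxon, reads in frac.counts.items():
                    heavy[taxon] = heavy.get(taxon, 0) + reads
    pseudo_results = [
        RoorResult(t, 1.0, 1.0, 1.0, True, bool(c))
        for t, c in zip(consensus["taxon"], consensus["consensus_labeled"])
    ]
    community = labeled_community_table(pseudo_results, heavy,
                                        config.dna.min_rel_abundance)
    out["community"] = write_table(
        community, outdir / "labeled_community.tsv",
        {**prov, "min_rel_abundance": config.dna.min_rel_abundance})
    return out


def run_plfa_stage(config: RunConfig, outdir: Path) -> dict[str, Path]:
    if config.plfa.input is None:
        raise DataError("plfa stage requested but no input table configured")
    pairs = frame_to_plfa_pairs(read_table(config.plfa.input))
    if not pairs:
        raise DataError("no T0/Tend lipid pairs found in the PLFA table")
    p = config.plfa
    rate_rows, call_rows = [], []
    for t0, tend in pairs:
        r13 = incorporation_rate(t0, tend, "13C", p.duration_days,
                                 clamp=p.clamp_negative)
        rd = incorporation_rate(t0, tend, "D", p.duration_days,
                                clamp=p.clamp_negative,
                                d_inventory=p.d_inventory)  # type: ignore[arg-type]
        for r in (r13, rd):
            rate_rows.append({
                "plfa_name": r.name.raw, "isotope": r.isotope,
                "rate_pmol_l_day": r.rate, "produced": r.c_produced,
                "excess_atom_fraction": r.delta_f, "clamped": r.clamped,
            })
        try:
            call = ra_rt(r13, rd, p.f13c_dic, p.fd_substrate,
                         p.heterotrophic_max, p.autotrophic_min)
            call_rows.append({
                "plfa_name": call.name.raw, "ra": call.ra, "rt": call.rt,
                "ra_rt": call.ra_rt, "call": call.call,
            })
        except UndefinedRatioError:
            call_rows.append({"plfa_name": t0.name.raw, "ra": r13.rate,
                              "rt": 0.0, "ra_rt": float("nan"),
                              "call": "undefined"})
    prov = {"duration_days": p.duration_days, "f13c_dic": p.f13c_dic,
            "fd_substrate": p.fd_substrate, "d_inventory": p.d_inventory,
            "clamp_negative": p.clamp_negative,
            "heterotrophic_max": p.heterotrophic_max,
            "autotrophic_min": p.autotrophic_min, "seed": config.seed}
    return {
        "rates": write_table(pd.DataFrame(rate_rows), outdir / "plfa_rates.csv",
                             prov),
        "trophic": write_table(pd.DataFrame(call_rows),
                               outdir / "plfa_trophic.csv", prov),
    }


def run_metab_stage(config: RunConfig, outdir: Path) -> dict[str, Path]:
    if config.metab.input is None:
        raise DataError("metab stage requested but no peak list configured")
    df = read_table(config.metab.input)
    m = config.metab
    assignments = []
    rows = []
    for fid, grp in df.groupby("feature_id", sort=True):
        peaks = [Peak(float(r.mz), float(r.intensity),
                      None if pd.isna(r.rt) else float(r.rt))
                 for r in grp.itertuples()]
        base = max(peaks, key=lambda pk: pk.intensity)
        series = match_series(base, peaks, m.max_k, m.tol_ppm)
        assignment = assign_labels(series, m.min_intensity_frac, str(fid))
        assignments.append(assignment)
        rows.append({
            "feature_id": fid, "base_mz": series.base_mz,
            "max_k13c": series.max_k13c, "max_kd": series.max_kd,
            "labeled_13c": assignment.labeled_13c,
            "labeled_d": assignment.labeled_d,
            "cd3_transfer": assignment.cd3_transfer,
            "n_cd3_groups": assignment.n_cd3_groups,
            "n_ambiguous_peaks": len(series.ambiguous),
        })
    prov = {"tol_ppm": m.tol_ppm, "max_k": m.max_k,
            "min_intensity_frac": m.min_intensity_frac, "seed": config.seed}
    out = {
        "assignments": write_table(pd.DataFrame(rows),
                                   outdir / "label_assignments.csv", prov),
        "census": write_table(
            pd.DataFrame([count_label_census(assignments)]),
            outdir / "label_census.csv", prov),
    }
    if m.consumption_areas:
        cons = [dataclasses.asdict(
                    substrate_consumption(float(areas[0]), float(areas[1]),
                                          compound))
                for compound, areas in m.consumption_areas.items()]
        out["consumption"] = write_table(pd.DataFrame(cons),
                                         outdir / "consumption.csv", prov)
    return out


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run the configured stages and write a run manifest.

    When a scenario preset is set and a stage has no input path, synthetic
    inputs are generated first (under ``<outdir>/synthetic``) and wired in.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    need_synth = any(getattr(config, s).input is None for s in config.stages)
    if need_synth and config.scenario is not None:
        synth = simulate_inputs(config, outdir / "synthetic")
        if config.dna.input is None and "dna" in config.stages:
            config.dna.input = str(synth["dna"])
        if config.plfa.input is None and "plfa" in config.stages:
            config.plfa.input = str(synth["plfa"])
        if config.metab.input is None and "metab" in config.stages:
            config.metab.input = str(synth["metab"])

    outputs: dict[str, dict[str, str]] = {}
    runners = {"dna": run_dna_stage, "plfa": run_plfa_stage,
               "metab": run_metab_stage}
    for stage in config.stages:
        stage_out = runners[stage](config, outdir)
        outputs[stage] = {k: str(v) for k, v in stage_out.items()}

    inputs = {s: getattr(config, s).input for s in config.stages
              if getattr(config, s).input}
    from .isotopes import DEFAULT_CONSTANTS

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "isotope_constants": DEFAULT_CONSTANTS.as_dict(),
        "scenario": config.scenario,
        "parameters": config.to_dict(),
        "input_checksums": {s: sha256_of(p) for s, p in inputs.items()},
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest
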