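"""Generators: determinism, null behavior, and closed-loop recovery."""

import numpy as np
import pandas as pd
import pytest

from dualsip.dna import roor
from dualsip.io import frame_to_plfa_pairs
from dualsip.metabolites import Peak, assign_labels, match_series
from dualsip.plfa import incorporation_rate, ra_rt
from dualsip.simulate import (
    CommunitySpec,
    FeatureSpec,
    LabelPools,
    LipidProducer,
    TaxonSpec,
    generate_gradient,
    generate_peaklists,
    generate_plfa,
    null_community_spec,
    scenario_preset,
    spiked_community_spec,
)


class TestGradientGenerator:
    def test_deterministic_in_seed(self):
        spec = spiked_community_spec(n_taxa=20, seed=3)
        b1, t1 = generate_gradient(spec, seed=11)
        b2, t2 = generate_gradient(spec, seed=11)
        for f1, f2 in zip(b1.labeled_replicates[0], b2.labeled_replicates[0]):
            assert dict(f1.counts) == dict(f2.counts)
        assert t1 == t2

    def test_different_seed_differs(self):
        spec = spiked_community_spec(n_taxa=20, seed=3)
        b1, _ = generate_gradient(spec, seed=11)
        b2, _ = generate_gradient(spec, seed=12)
        c1 = [dict(f.counts) for f in b1.labeled_replicates[0]]
        c2 = [dict(f.counts) for f in b2.labeled_replicates[0]]
        assert c1 != c2

    def test_labeled_taxon_shifts_heavy(self):
        """A fully labeled taxon's heavy/light odds exceed the control's."""
        spec = spiked_community_spec(read_depth=100_000, seed=1)
        bottles, _ = generate_gradient(spec, seed=1)
        res = roor("labeled", bottles.labeled_replicates[0],
                   bottles.control_bottle)
        assert res.roor > 1

    def test_null_taxa_are_exchangeable_in_distribution(self):
        """With no labeling anywhere, RoOR has median ~1 across taxa."""
        roors = []
        for seed in range(1, 51):
            spec = null_community_spec(n_taxa=30, alpha=0.5, seed=seed)
            bottles, _ = generate_gradient(spec, seed=seed + 100)
            for taxon in [t.name for t in spec.taxa]:
                try:
                    r = roor(taxon, bottles.labeled_replicates[0],
                             bottles.control_bottle)
                except Exception:
                    continue
                roors.append(r.roor)
        assert 0.8 <= np.median(roors) <= 1.25

    def test_truth_records_labeled_taxa(self):
        spec = spiked_community_spec(seed=0)
        _, truth = generate_gradient(spec, seed=5)
        assert dict(truth.records) == {"labeled": 1.0}

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            CommunitySpec(taxa=[TaxonSpec("a", 1.0, 0.5)],
                          density_grid=[1.70, 1.70])

    def test_abundances_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CommunitySpec(taxa=[TaxonSpec("a", 0.7, 0.5)])


HET = LipidProducer({"18:1w7": 0.7, "16:0": 0.3}, growth=30.0,
                    dic_fraction=0.0)
AUTO = LipidProducer({"16:0": 1.0}, growth=20.0, dic_fraction=1.0)


def analyze(table, duration=84.0, pools=LabelPools()):
    out = {}
    for t0, tend in frame_to_plfa_pairs(table):
        r13 = incorporation_rate(t0, tend, "13C", duration)
        rd = incorporation_rate(t0, tend, "D", duration)
        out[t0.name.raw] = (r13, rd,
                            ra_rt(r13, rd, pools.f13c_dic, pools.fd_substrate))
    return out


class TestPlfaGenerator:
    def test_zero_growth_produces_nothing(self):
        prod = LipidProducer({"16:0": 1.0}, growth=0.0, dic_fraction=0.5)
        table, truth = generate_plfa([prod], seed=1)
        t0 = table[table.timepoint == "T0"].conc_pmol_per_l
        tend = table[table.timepoint == "Tend"].conc_pmol_per_l
        assert (t0.values == tend.values).all()
        assert truth.records[0][3] == 0.0  # no 13C rate

    def test_zero_noise_round_trip_exact(self):
        """The incorporation-rate formula recovers the generator's configured
        rates to < 1e-9 relative at zero noise."""
        mixed = LipidProducer({"16:0": 0.5, "a15:0": 0.5}, growth=25.0,
                              dic_fraction=0.4)
        table, truth = generate_plfa([mixed, HET], noise_sd_delta=0.0, seed=1)
        rates = analyze(table)
        for name, growth, a, r13_true, rd_true in truth.records:
            r13, rd, _ = rates[name]
            assert r13.rate == pytest.approx(r13_true, rel=1e-9)
            assert rd.rate == pytest.approx(rd_true, rel=1e-9)

    def test_pure_heterotroph_classified(self):
        table, _ = generate_plfa([HET], noise_sd_delta=2.0, seed=7)
        for _, _, call in analyze(table).values():
            assert call.ra_rt <= 0.3

    def test_pure_autotroph_classified(self):
        table, _ = generate_plfa([AUTO], noise_sd_delta=2.0, seed=7)
        (_, _, call), = analyze(table).values()
        assert call.ra_rt >= 0.8
        assert call.ra_rt == pytest.approx(1.0, abs=0.05)

    def test_noisy_recovery_within_ten_percent(self):
        mixed = LipidProducer({"16:0": 1.0}, growth=25.0, dic_fraction=0.4)
        errors = []
        for seed in range(30):
            table, truth = generate_plfa([mixed], noise_sd_delta=2.0,
                                         seed=seed)
            (_, _, r13_true, rd_true) = truth.records[0][1:]
            r13, rd, _ = analyze(table)[truth.records[0][0]]
            errors.append(abs(r13.rate - r13_true) / r13_true)
            errors.append(abs(rd.rate - rd_true) / rd_true)
        assert np.quantile(errors, 0.95) < 0.10

    def test_deterministic_in_seed(self):
        table1, _ = generate_plfa([HET], noise_sd_delta=2.0, seed=3)
        table2, _ = generate_plfa([HET], noise_sd_delta=2.0, seed=3)
        pd.testing.assert_frame_equal(table1, table2)


class TestPeaklistGenerator:
    def test_closed_loop_cd3(self):
        table, _ = generate_peaklists(
            [FeatureSpec("f1", 200.0, k13c=0, kd=3)], ppm_noise=0.0, seed=1)
        peaks = [Peak(r.mz, r.intensity) for r in table.itertuples()]
        base = max(peaks, key=lambda p: p.intensity)
        a = assign_labels(match_series(base, peaks, 12, 2.0))
        assert a.cd3_transfer and a.n_cd3_groups == 1

    def test_truth_records_label_counts(self):
        feats = [FeatureSpec(f"f{i}", 150.0 + 10 * i, k13c=i % 3, kd=i % 4)
                 for i in range(8)]
        _, truth = generate_peaklists(feats, seed=0)
        assert truth.records == tuple((f.feature_id, f.k13c, f.kd)
                                      for f in feats)

    def test_zero_noise_fixed_seed_identical(self):
        feats = [FeatureSpec("f", 180.0, 2, 3)]
        t1, _ = generate_peaklists(feats, ppm_noise=0.0, seed=4)
        t2, _ = generate_peaklists(feats, ppm_noise=0.0, seed=4)
        pd.testing.assert_frame_equal(t1, t2)

    def test_noisy_recovery_with_adequate_resolution(self):
        """Label counts are recovered through ppm-scale noise for masses
        where the instrument separates the two shift types."""
        rng = np.random.default_rng(0)
        n_ok = 0
        n = 200
        feats = [FeatureSpec(f"f{i}", float(rng.uniform(120, 450)),
                             k13c=int(rng.integers(0, 4)),
                             kd=int(rng.integers(0, 4)))
                 for i in range(n)]
        table, truth = generate_peaklists(feats, ppm_noise=0.5, seed=1)
        for fid, k13, kd in truth.records:
            sub = table[table.feature_id == fid]
            peaks = [Peak(r.mz, r.intensity) for r in sub.itertuples()]
            base = max(peaks, key=lambda p: p.intensity)
            series = match_series(base, peaks, 12, 3.0)
            if series.max_k13c == k13 and series.max_kd == kd:
                n_ok += 1
        assert n_ok / n >= 0.99


class TestScenarios:
    @pytest.mark.parametrize("name", ["h41-va", "h43-dual", "h51-dual",
                                      "h52-co2"])
    def test_presets_complete(self, name):
        preset = scenario_preset(name)
        assert {"community", "producers", "treatment", "well",
                "duration_days", "design"} <= set(preset)
        n_reps = preset["community"].n_labeled_replicates
        assert n_reps == (2 if preset["design"] == "duplicates" else 3)

    def test_unknown_scenario(self):
        with pytest.raises(KeyError):
            scenario_preset("h99")
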