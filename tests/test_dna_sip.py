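"""DNA-SIP: heavy/light splitting, odds ratios, RoOR calls, consensus."""

import numpy as np
import pytest

from dualsip.dna import (
    DegenerateSplitError,
    DesignMismatchError,
    DivisionDomainError,
    FractionProfile,
    RoorResult,
    SplitRule,
    consensus_call,
    labeled_community_table,
    odds_ratio_2x2,
    roor,
    split_heavy_light,
    taxon_odds,
)


def make_bottle(densities, heavy_counts, light_counts, threshold=1.715):
    """Two-taxon bottle: 'focal' vs 'rest', with specified per-side totals."""
    heavy_ids = [i for i, d in enumerate(densities) if d > threshold]
    light_ids = [i for i, d in enumerate(densities) if d <= threshold]
    fractions = []
    for i, d in enumerate(densities):
        if i in heavy_ids:
            a, b = heavy_counts
            n = len(heavy_ids)
            pos = heavy_ids.index(i)
        else:
            a, b = light_counts
            n = len(light_ids)
            pos = light_ids.index(i)
        # spread side totals over the side's fractions, remainder on the first
        counts = {
            "focal": a // n + (a % n if pos == 0 else 0),
            "rest": b // n + (b % n if pos == 0 else 0),
        }
        fractions.append(FractionProfile(i, d, 1.0, counts))
    return fractions


DENSITIES = [1.69, 1.70, 1.71, 1.72, 1.73]


class TestSplitHeavyLight:
    def test_density_threshold(self):
        bottle = make_bottle(DENSITIES, (10, 10), (10, 10))
        split = split_heavy_light(bottle, SplitRule.density_threshold(1.715))
        heavy_densities = {DENSITIES[i] for i in split.heavy_fraction_ids}
        assert heavy_densities == {1.72, 1.73}

    def test_top_k_takes_densest(self):
        bottle = make_bottle(DENSITIES, (10, 10), (10, 10))
        split = split_heavy_light(bottle, SplitRule.top_k(2))
        assert {DENSITIES[i] for i in split.heavy_fraction_ids} == {1.72, 1.73}

    def test_uniform_density_degenerate(self):
        fractions = [FractionProfile(i, 1.70, 1.0, {"t": 1}) for i in range(4)]
        with pytest.raises(DegenerateSplitError):
            split_heavy_light(fractions, SplitRule.density_threshold(1.715))

    def test_threshold_outside_range_degenerate(self):
        bottle = make_bottle(DENSITIES, (10, 10), (10, 10))
        with pytest.raises(DegenerateSplitError):
            split_heavy_light(bottle, SplitRule.density_threshold(1.60))


class TestOddsRatio:
    @pytest.mark.parametrize("cells,p,expected", [
        ((10, 10, 10, 10), 0.0, 1.0),                       # symmetric table
        ((20, 80, 5, 95), 0.0, 4.75),                        # hand arithmetic
        ((0, 100, 10, 90), 0.5, (0.5 / 100.5) / (10.5 / 90.5)),  # Haldane
    ])
    def test_known_tables(self, cells, p, expected):
        assert odds_ratio_2x2(*cells, pseudocount=p) == pytest.approx(expected)

    def test_zero_cell_without_pseudocount_errors(self):
        with pytest.raises(DivisionDomainError):
            odds_ratio_2x2(0, 100, 10, 90, pseudocount=0.0)

    def test_pseudocount_untouched_when_no_zero_cell(self):
        # exact arithmetic preserved for complete tables
        assert odds_ratio_2x2(20, 80, 5, 95, pseudocount=0.5) == 4.75

    def test_brute_force_equivalence_on_random_tables(self):
        """taxon_odds through pooled fractions equals direct 2x2 arithmetic
        on 1000 random tables, with and without zero cells."""
        rng = np.random.default_rng(42)
        rule = SplitRule.density_threshold(1.715)
        for _ in range(1000):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, 4))
            if b == 0 or d == 0 or (a + c) == 0:
                continue  # focal absent or empty side; covered by error tests
            bottle = make_bottle(DENSITIES, (a, b), (c, d))
            split = split_heavy_light(bottle, rule)
            got = taxon_odds("focal", split, bottle, pseudocount=0.5)
            if 0 in (a, b, c, d):
                aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
            else:
                aa, bb, cc, dd = a, b, c, d
            assert got == pytest.approx((aa / bb) / (cc / dd), rel=1e-12)

    def test_swapping_sides_inverts_odds(self):
        bottle = make_bottle(DENSITIES, (20, 80), (5, 95))
        rule = SplitRule.density_threshold(1.715)
        split = split_heavy_light(bottle, rule)
        forward = taxon_odds("focal", split, bottle, pseudocount=0)
        swapped = type(split)(split.light_fraction_ids,
                              split.heavy_fraction_ids, split.rule)
        assert taxon_odds("focal", swapped, bottle,
                          pseudocount=0) == pytest.approx(1 / forward)

    def test_depth_invariance(self):
        """Multiplying all counts in a bottle by a constant leaves the OR
        unchanged when no pseudocount fires."""
        rule = SplitRule.density_threshold(1.715)
        base = make_bottle(DENSITIES, (120, 500), (100, 600))
        scaled = make_bottle(DENSITIES, (1200, 5000), (1000, 6000))
        s1, s2 = (split_heavy_light(b, rule) for b in (base, scaled))
        assert taxon_odds("focal", s2, scaled) == pytest.approx(
            taxon_odds("focal", s1, base), rel=1e-3)


class TestRoor:
    def test_identical_bottles_give_unity(self):
        bottle = make_bottle(DENSITIES, (20, 80), (20, 80))
        res = roor("focal", bottle, bottle)
        assert res.roor == pytest.approx(1.0)
        assert not res.called_labeled

    def test_composed_odds_ratios(self):
        labeled = make_bottle(DENSITIES, (20, 80), (5, 95))
        control = make_bottle(DENSITIES, (10, 90), (10, 90))
        res = roor("focal", labeled, control)
        assert res.or_labeled == pytest.approx(4.75)
        assert res.or_control == pytest.approx(1.0)
        assert res.roor == pytest.approx(4.75)
        assert res.called_labeled  # all four pools have >= 5 focal reads

    def test_read_filter_blocks_call_regardless_of_roor(self):
        labeled = make_bottle(DENSITIES, (40, 80), (5, 95))
        control = make_bottle(DENSITIES, (4, 90), (10, 90))  # 4 < 5 in heavy
        res = roor("focal", labeled, control)
        assert res.roor > 1
        assert not res.passes_read_filter
        assert not res.called_labeled

    def test_absent_taxon_rejected(self):
        bottle = make_bottle(DENSITIES, (20, 80), (5, 95))
        with pytest.raises(Exception, match="absent"):
            roor("ghost", bottle, bottle)


def _res(called):
    return RoorResult("t", 2.0, 1.0, 2.0, True, called)


class TestConsensus:
    @pytest.mark.parametrize("calls,design,expected", [
        ([True, True], "duplicates", True),
        ([True, False], "duplicates", False),
        ([True, True, False], "triplicates", True),   # two of three
        ([True, False, False], "triplicates", False),
        ([True, True, True], "triplicates", True),
    ])
    def test_rules(self, calls, design, expected):
        results = [_res(c) for c in calls]
        assert consensus_call(results, design) is expected

    def test_wrong_replicate_count_rejected(self):
        with pytest.raises(DesignMismatchError):
            consensus_call([_res(True)], "duplicates")


class TestLabeledCommunityTable:
    def test_single_labeled_taxon(self):
        table = labeled_community_table([_resn("a", True)], {"a": 50})
        assert table["rel_abundance"].tolist() == [1.0]

    def test_direct_proportions(self):
        results = [_resn(n, True) for n in ("a", "b", "c")]
        table = labeled_community_table(results, {"a": 50, "b": 30, "c": 20})
        assert dict(zip(table["taxon"], table["rel_abundance"])) == pytest.approx(
            {"a": 0.5, "b": 0.3, "c": 0.2})

    def test_rare_taxon_folded_into_other(self):
        results = [_resn(n, True) for n in ("a", "b")]
        table = labeled_community_table(results, {"a": 992, "b": 8},
                                        min_rel_abundance=0.01)
        assert set(table["taxon"]) == {"a", "other"}
        assert table["rel_abundance"].sum() == pytest.approx(1.0)

    def test_empty_when_nothing_labeled(self):
        table = labeled_community_table([_resn("a", False)], {"a": 10})
        assert table.empty


def _resn(name, called):
    return RoorResult(name, 2.0, 1.0, 2.0, True, called)
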