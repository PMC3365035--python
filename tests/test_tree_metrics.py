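"""Tests for LTT extraction, gamma, stemminess and root-gap statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phyloerosion import (
    LTTSeries,
    UndefinedStatisticError,
    build_tree,
    from_newick,
    ltt,
    ncs,
    pybus_harvey_gamma,
    root_age,
    root_gap_distances,
    yule_ltt,
)

from _oracles import sweep_gamma
from conftest import SUITE_SEED, random_log

WORKED = "((G1:70.0,G3:70.0):20.0,G2:90.0):10.0;"


class TestLTT:
    def test_worked_example_intervals(self):
        series = ltt(from_newick(WORKED))
        assert list(series.branching_ages) == [10, 30]
        assert list(series.intervals()) == [20, 70]

    def test_multifurcation_contributes_zero_length_interval(self):
        tree = from_newick("(A:5,B:5,C:5):5;")  # root trifurcation at age 5
        series = ltt(tree)
        assert list(series.branching_ages) == [5, 5]
        assert list(series.intervals()) == [0, 5]

    def test_two_tip_interval_spans_root_to_present(self):
        series = ltt(from_newick("(A:7,B:7):3;"))
        assert list(series.intervals()) == [7]
        assert series.root_age == 3


class TestGamma:
    def test_symmetric_three_tip_case_is_zero(self):
        series = LTTSeries(branching_ages=[0.0, 3.0], sample_time=5.0, n=3)
        # g2=3, g3=2: A_2 = 6 = T/2
        assert pybus_harvey_gamma(series) == pytest.approx(0.0, abs=1e-12)

    def test_equal_intervals_four_tips(self):
        series = LTTSeries(branching_ages=[0.0, 1.0, 2.0], sample_time=3.0, n=4)
        assert pybus_harvey_gamma(series) == pytest.approx(-0.5443, abs=1e-4)

    def test_worked_three_tip_tree(self):
        assert pybus_harvey_gamma(ltt(from_newick(WORKED))) == pytest.approx(
            -1.1778, abs=1e-4
        )

    def test_undefined_below_three_tips(self):
        with pytest.raises(UndefinedStatisticError):
            pybus_harvey_gamma(LTTSeries([5.0], sample_time=9.0, n=2))

    def test_zero_height_tree_is_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            pybus_harvey_gamma(LTTSeries([4.0, 4.0], sample_time=4.0, n=3))

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_invariant_to_uniform_time_rescaling(self, scale):
        ages = np.array([2.0, 5.0, 11.0, 13.0])
        base = LTTSeries(ages, sample_time=20.0, n=5)
        scaled = LTTSeries(ages * scale, sample_time=20.0 * scale, n=5)
        assert pybus_harvey_gamma(scaled) == pytest.approx(
            pybus_harvey_gamma(base), rel=1e-9
        )

    def test_matches_unit_step_sweep_oracle_on_random_trees(self):
        rng = np.random.default_rng(SUITE_SEED + 10)
        checked = 0
        while checked < 50:
            log = random_log(rng, n_genotypes=12)
            if log.extant_at(100).size < 3:
                continue
            series = ltt(build_tree(log, 100))
            expected = sweep_gamma(series.branching_ages, series.sample_time)
            assert pybus_harvey_gamma(series) == pytest.approx(
                expected, rel=1e-9, abs=1e-9
            )
            checked += 1

    def test_branching_near_tips_increases_gamma(self):
        """Moving branching events tipward (holding n and depth) raises gamma;
        verified against the sweep oracle on exhaustive small-age grids."""
        sample = 12
        for a2 in range(0, 9, 2):
            for a3 in range(a2, 10, 2):
                for b3 in range(a3 + 1, 11):
                    g_old = pybus_harvey_gamma(
                        LTTSeries([float(a2), float(a3)], sample_time=sample, n=3)
                    )
                    g_new = pybus_harvey_gamma(
                        LTTSeries([float(a2), float(b3)], sample_time=sample, n=3)
                    )
                    assert g_new > g_old
                    assert g_new == pytest.approx(
                        sweep_gamma([a2, b3], sample), rel=1e-9, abs=1e-9
                    )

    def test_yule_trees_calibrate_to_standard_normal(self):
        """Mean gamma of pure-birth trees within 3 SE of 0 and variance near 1
        (the statistic's standard-normal limit)."""
        rng = np.random.default_rng(SUITE_SEED + 11)
        vals = np.array(
            [pybus_harvey_gamma(yule_ltt(50, rng)) for _ in range(500)]
        )
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se
        assert 0.8 <= vals.var(ddof=1) <= 1.25


class TestNCS:
    def test_balanced_four_tip_tree(self):
        tree = from_newick("((A:1,B:1):2,(C:1,D:1):2):0;")
        assert ncs(tree, "rohlf1990").value == pytest.approx(0.5)
        assert ncs(tree, "inverse-ratio").value == pytest.approx(1.0)

    def test_worked_three_tip_tree(self):
        res = ncs(from_newick(WORKED), "rohlf1990")
        assert res.value == pytest.approx(0.125)
        assert res.n_internal_nodes == 1

    def test_basal_stem_lengthening_raises_stemminess(self):
        # same sample time, node age moved 30 -> 90: stem 20 -> 80
        stretched = from_newick("((G1:10.0,G3:10.0):80.0,G2:90.0):10.0;")
        assert ncs(stretched, "rohlf1990").value == pytest.approx(0.8)
        assert ncs(stretched, "rohlf1990").value > ncs(
            from_newick(WORKED), "rohlf1990"
        ).value

    def test_rohlf_variant_bounded_in_unit_interval(self):
        rng = np.random.default_rng(SUITE_SEED + 12)
        checked = 0
        while checked < 30:
            log = random_log(rng, n_genotypes=14)
            if log.extant_at(100).size < 3:
                continue
            try:
                res = ncs(build_tree(log, 100), "rohlf1990")
            except UndefinedStatisticError:
                continue
            assert 0.0 <= res.value <= 1.0
            checked += 1

    def test_zero_length_stem_skipped_for_inverse_ratio(self):
        tree = from_newick("((A:2,B:2):0.0,(C:1,D:1):1.0):1;")
        res = ncs(tree, "inverse-ratio")
        assert res.n_skipped == 1
        assert res.n_internal_nodes == 1
        assert res.value == pytest.approx(2.0)  # (1+1)/1 for the other node

    def test_undefined_without_internal_non_root_node(self):
        with pytest.raises(UndefinedStatisticError):
            ncs(from_newick("(A:1,B:1):0;"))
        with pytest.raises(UndefinedStatisticError):
            ncs(from_newick("(A:5,B:5,C:5):5;"))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ncs(from_newick(WORKED), "bogus")


class TestRootMetrics:
    def test_root_age_and_ordering(self):
        tree = from_newick(WORKED)
        assert root_age(tree) == 10
        assert root_age(tree) < min(
            n.age for n in tree.internal_nodes() if n is not tree.root
        )

    def test_root_gap_distances_worked_example(self):
        # add a third node at age 50 under the node at 30
        tree = from_newick("(((G1:50,G4:50):20,G3:70):20,G2:90):10;")
        d1, d2 = root_gap_distances(tree)
        assert (d1, d2) == (20, 40)

    def test_multifurcating_root_gives_zero_first_gap(self):
        d1, _ = root_gap_distances(from_newick("(A:5,B:5,C:5):5;"))
        assert d1 == 0

    def test_three_tip_tree_has_no_second_gap(self):
        d1, d2 = root_gap_distances(from_newick(WORKED))
        assert d1 == 20
        assert d2 is None
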