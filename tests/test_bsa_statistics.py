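"""Marker statistics against closed forms and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bulkmap import bsa_statistics as stats
from oracles import fisher_two_tailed_exact, g_closed_form


class TestSnpIndex:
    @pytest.mark.parametrize(
        "a, b, oriented, expected",
        [
            (8, 2, True, 0.8),
            (0, 12, True, 0.0),
            (3, 7, False, 0.7),
            (7, 3, False, 0.7),
            (5, 5, False, 0.5),
        ],
    )
    def test_values(self, a, b, oriented, expected):
        assert stats.snp_index(a, b, oriented) == pytest.approx(expected)

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError):
            stats.snp_index(0, 0)


class TestDelta:
    @pytest.mark.parametrize(
        "top, bottom, oriented, expected",
        [(0.9, 0.1, True, 0.8), (0.5, 0.5, True, 0.0), (0.2, 0.9, False, 0.7),
         (0.1, 0.9, True, -0.8)],
    )
    def test_values(self, top, bottom, oriented, expected):
        assert stats.delta_snp_index(top, bottom, oriented) == pytest.approx(expected)


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (((5, 5), (5, 5)), 1.0),
            (((10, 0), (0, 10)), 2 / 184756),  # both extreme tables
            (((0, 0), (3, 7)), 1.0),  # zero margin convention
            (((3, 0), (0, 0)), 1.0),
        ],
    )
    def test_reference_values(self, table, expected):
        assert stats.fisher_exact_two_tailed(table) == pytest.approx(expected, rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.tuples(*(st.integers(0, 25),) * 4))
    def test_matches_exact_enumeration(self, cells):
        a, b, c, d = cells
        got = stats.fisher_exact_two_tailed(((a, b), (c, d)))
        want = fisher_two_tailed_exact(a, b, c, d)
        assert got == pytest.approx(want, abs=1e-9)
        assert 0.0 < got <= 1.0


class TestGStatistic:
    def test_closed_form_extreme(self):
        assert stats.g_statistic(((10, 0), (0, 10))) == pytest.approx(
            40 * math.log(2), abs=1e-9
        )

    def test_zero_for_balanced_table(self):
        assert stats.g_statistic(((5, 5), (5, 5))) == 0.0

    def test_symmetry_under_swaps(self):
        t = ((7, 3), (2, 11))
        swapped_rows = ((2, 11), (7, 3))
        swapped_cols = ((3, 7), (11, 2))
        assert stats.g_statistic(t) == pytest.approx(stats.g_statistic(swapped_rows))
        assert stats.g_statistic(t) == pytest.approx(stats.g_statistic(swapped_cols))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.tuples(*(st.integers(0, 40),) * 4))
    def test_matches_scalar_closed_form(self, cells):
        a, b, c, d = cells
        t = ((a, b), (c, d))
        assert stats.g_statistic(t) == pytest.approx(g_closed_form(t), abs=1e-9)
        assert stats.g_statistic(t) >= 0.0


class TestEuclideanDistance:
    @pytest.mark.parametrize(
        "af_a, af_b, expected",
        [
            ((0.5, 0.5), (0.5, 0.5), 0.0),
            ((1.0, 0.0), (0.0, 1.0), math.sqrt(2)),
            ((0.75, 0.25), (0.25, 0.75), math.sqrt(2) * 0.5),
        ],
    )
    def test_values(self, af_a, af_b, expected):
        assert stats.euclidean_distance_marker(af_a, af_b) == pytest.approx(expected)


class TestEdWindow:
    def test_closed_forms(self):
        assert stats.ed_window_power([0.0] * 100) == 0.0
        assert stats.ed_window_power([math.sqrt(2)] * 100) == pytest.approx(4e8, rel=1e-12)

    def test_short_chromosome_yields_nothing(self):
        assert stats.ed_power_series([1.0] * 99).size == 0

    def test_sliding_by_one_marker(self):
        out = stats.ed_power_series(np.arange(105, dtype=float))
        assert out.size == 6
        assert out[0] == pytest.approx(sum(range(100)) ** 4)


class TestMovingAverage:
    def test_uniform_weights_equal_arithmetic_mean(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(
            stats.weighted_moving_average(v, None, 3),
            stats.weighted_moving_average(v, np.ones(4), 3),
        )

    def test_window_one_is_identity(self):
        v = np.array([0.3, 0.9, 0.1])
        np.testing.assert_allclose(stats.weighted_moving_average(v, [1, 2, 3], 1), v)

    def test_depth_weighting(self):
        out = stats.weighted_moving_average([0.2, 0.8], [10, 30], 2)
        assert out[0] == pytest.approx(0.65)

    def test_physical_mode_skips_empty_intervals(self):
        mids, avgs = stats.physical_window_average(
            [100, 200, 5100], [1.0, 3.0, 10.0], None, 1000
        )
        assert len(mids) == 2  # intervals 2..5 contain no markers
        assert avgs[0] == pytest.approx(2.0)
        assert avgs[1] == pytest.approx(10.0)


class TestBoost:
    def test_monotone_and_capped(self):
        assert stats.boost(0.9) > stats.boost(0.5) > stats.boost(0.0)
        assert stats.boost(0.0) == pytest.approx(1.0)
        assert np.isfinite(stats.boost(1.0))
        assert stats.boost(1.0) == 100.0
        assert stats.boost(0.999999, cap=10.0) == 10.0


class TestCiBounds:
    def test_reference_interval(self):
        lo, hi = stats.delta_ci_bounds((30, 30), (30, 30), alpha=0.05, n_tests=1)
        assert lo == pytest.approx(-0.1789, abs=2e-4)
        assert hi == pytest.approx(0.1789, abs=2e-4)

    def test_bonferroni_widens_interval(self):
        lo1, hi1 = stats.delta_ci_bounds((30, 30), (30, 30), n_tests=1)
        lo2, hi2 = stats.delta_ci_bounds((30, 30), (30, 30), n_tests=100)
        assert lo2 < lo1 and hi2 > hi1

    def test_degenerate_proportions(self):
        lo, hi = stats.delta_ci_bounds((0, 10), (0, 10))
        assert lo == 0.0 and hi == 0.0

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            stats.delta_ci_bounds((0, 0), (5, 5))


class TestBonferroniThreshold:
    def test_reference_values(self):
        assert stats.bonferroni_threshold(0.05, 1) == pytest.approx(1.30103, abs=1e-5)
        # -log10(0.05/151) = log10(3020)
        assert stats.bonferroni_threshold(0.05, 151) == pytest.approx(
            math.log10(3020), abs=1e-9
        )
        assert stats.bonferroni_threshold(0.05, 151) == pytest.approx(3.48001, abs=1e-5)

    def test_monotone_in_n_tests(self):
        ts = [stats.bonferroni_threshold(0.05, n) for n in (1, 2, 10, 151, 10000)]
        assert ts == sorted(ts) and len(set(ts)) == len(ts)


class TestSiteStatistics:
    def test_identity_ed_equals_sqrt2_delta(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = {
                "D": tuple(rng.integers(1, 100, 2)),
                "R": tuple(rng.integers(1, 100, 2)),
            }
            out = stats.site_statistics(counts, oriented=True, mode="mbs")
            assert out["ED"] == pytest.approx(
                math.sqrt(2) * abs(out["DELTA"]), abs=1e-12
            )

    def test_single_bulk_reports_index_only(self):
        out = stats.site_statistics({"R": (8, 2)}, oriented=True, mode="mbs")
        assert out == {"SNPIDX_R": pytest.approx(0.8)}

    def test_unoriented_delta_is_absolute(self):
        out = stats.site_statistics(
            {"D": (2, 8), "R": (9, 1)}, oriented=False, mode="mbs"
        )
        assert out["DELTA"] == pytest.approx(0.7)
        assert out["SNPIDX_R"] == pytest.approx(0.9)
        assert out["SNPIDX_D"] == pytest.approx(0.8)
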