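"""Bud-volume morphometrics: sibling CVs, regression, positional and growth tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multibud.budstats import (
    BudVolumeTable,
    GrowthSeries,
    distant_adjacent_analysis,
    exact_gof_pvalue,
    growth_rate_analysis,
    sibling_cv_stats,
    summed_fraction_fit,
)


def _table(mothers):
    """mothers: list of (mother_volume, [bud volumes], [labels] or None)."""
    ids, vols, buds, labels = [], [], [], []
    for i, m in enumerate(mothers):
        v, b = m[0], np.asarray(m[1], dtype=float)
        lab = tuple(m[2]) if len(m) > 2 and m[2] is not None else ("",) * len(b)
        ids.append(f"m{i}")
        vols.append(v)
        buds.append(b)
        labels.append(lab)
    return BudVolumeTable(
        mother_ids=tuple(ids),
        mother_volumes=np.asarray(vols),
        bud_volumes=tuple(buds),
        bud_labels=tuple(labels),
    )


class TestSiblingCV:
    def test_identical_siblings_cv_zero(self):
        stats = sibling_cv_stats(_table([(20, [5, 5])]))
        assert stats.per_mother_cv["m0"] == 0.0

    def test_two_unequal_siblings(self):
        stats = sibling_cv_stats(_table([(20, [2, 4])]))
        assert stats.per_mother_cv["m0"] == pytest.approx(np.sqrt(2) / 3, rel=1e-12)

    def test_single_bud_counted_not_cv(self):
        stats = sibling_cv_stats(_table([(20, [5]), (20, [3, 3])]))
        assert stats.n_single_bud == 1
        assert "m0" not in stats.per_mother_cv

    def test_class_grouping(self):
        stats = sibling_cv_stats(
            _table([(9, [1, 2]), (9, [1, 2, 3]), (9, [1] * 6), (9, [2] * 5)])
        )
        assert stats.class_counts == {"2": 1, "3": 1, "4": 0, ">=5": 2}

    def test_population_cv_exceeds_sibling_cv_with_between_mother_spread(self):
        mothers = [(10 * s, [s, s * 1.05]) for s in (1, 3, 9, 27)]
        stats = sibling_cv_stats(_table(mothers))
        assert stats.population_cv > stats.mean_cv

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError, match="m0"):
            _table([(20, [5, -1])])


class TestSummedFractionFit:
    def test_noise_free_slope_exact(self):
        f = 0.45
        mothers = [(v, [f * v / 3] * 3) for v in (30, 100, 300, 1000)]
        fit = summed_fraction_fit(_table(mothers))
        assert fit["slope"] == pytest.approx(f, rel=1e-12)
        assert fit["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert fit["r_squared"] == pytest.approx(1.0, rel=1e-12)

    def test_rejects_too_few_or_degenerate(self):
        with pytest.raises(ValueError, match="3 mothers"):
            summed_fraction_fit(_table([(10, [1]), (20, [2])]))
        with pytest.raises(ValueError, match="degenerate"):
            summed_fraction_fit(_table([(10, [1])] * 4))


class TestDistantAdjacent:
    def test_printed_example_fraction_and_chi2(self):
        """20 of 49 distant-largest: 41%, chi2 ≈ 1.234, p ≈ 0.267."""
        mothers = []
        for i in range(49):
            if i < 20:
                mothers.append((9, [1.0, 1.0, 2.0], ["adjacent", "adjacent", "distant"]))
            else:
                mothers.append((9, [2.0, 1.0, 1.0], ["adjacent", "adjacent", "distant"]))
        res = distant_adjacent_analysis(_table(mothers))
        assert res["n_distant_largest"] == 20
        assert round(100 * res["fraction_distant_largest"]) == 41
        assert res["chi2"] == pytest.approx(1.2345, abs=1e-3)
        assert res["p_value"] == pytest.approx(0.2666, abs=1e-3)

    def test_exact_null_gives_chi2_zero(self):
        mothers = (
            [(9, [1, 1, 2], ["adjacent", "adjacent", "distant"])] * 3
            + [(9, [2, 1, 1], ["adjacent", "adjacent", "distant"])] * 6
        )
        res = distant_adjacent_analysis(_table(mothers))
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0)

    def test_tie_counts_as_not_largest_and_flagged(self):
        mothers = [(9, [2.0, 1.0, 2.0], ["adjacent", "adjacent", "distant"])]
        res = distant_adjacent_analysis(_table(mothers))
        assert res["n_distant_largest"] == 0
        assert res["ties"] == ["m0"]

    def test_rejects_missing_or_duplicate_distant(self):
        with pytest.raises(ValueError, match="m0"):
            distant_adjacent_analysis(
                _table([(9, [1, 1, 1], ["adjacent", "adjacent", "adjacent"])])
            )

    @pytest.mark.parametrize("n,k", [(6, 0), (6, 2), (9, 5), (12, 4), (12, 9)])
    def test_chi2_against_exact_enumeration(self, n, k):
        """The df=1 chi-square tail tracks the exact binomial enumeration at small n."""
        mothers = []
        for i in range(n):
            buds = [1.0, 1.0, 2.0] if i < k else [2.0, 1.0, 1.0]
            mothers.append((9, buds, ["adjacent", "adjacent", "distant"]))
        res = distant_adjacent_analysis(_table(mothers))
        exact = exact_gof_pvalue(k, n)
        # the continuous approximation is coarsest in extreme tails at tiny n
        assert res["p_value"] == pytest.approx(exact, abs=0.15)

    def test_relative_volumes_by_label(self):
        mothers = [(9, [1.0, 1.0, 2.5], ["adjacent", "adjacent", "distant"])]
        res = distant_adjacent_analysis(_table(mothers))
        assert res["relative_volumes"]["distant"][0] == pytest.approx(2.5 / 1.5)


class TestGrowthRates:
    def _series(self, trajs, times=None):
        times = times if times is not None else np.arange(0.0, 100.0, 5.0)
        return GrowthSeries(
            mother_ids=("g0",), times=(times,), trajectories=(np.asarray(trajs),)
        )

    def test_equal_rates_cv_zero_no_compensation(self):
        t = np.arange(0.0, 100.0, 5.0)
        series = self._series([2 + 0.5 * t, 2 + 0.5 * t])
        res = growth_rate_analysis(series)
        m = res["per_mother"]["g0"]
        assert m["rate_cv"] == pytest.approx(0.0, abs=1e-12)
        assert not m["compensation"]

    def test_persistent_ratio_not_flagged(self):
        t = np.arange(0.0, 100.0, 5.0)
        series = self._series([2 + 0.5 * t, 2 + 1.0 * t])
        res = growth_rate_analysis(series)
        assert not res["any_compensation"]

    def test_rate_doubling_midway_flagged(self):
        t = np.arange(0.0, 100.0, 5.0)
        slow = 2 + np.where(t <= 50, 0.5 * t, 25 + 1.0 * (t - 50))
        fast = 2 + 1.0 * t
        res = growth_rate_analysis(self._series([slow, fast]))
        assert res["any_compensation"]

    def test_short_series_skipped(self):
        t = np.array([0.0, 5.0, 10.0, 15.0])
        v = np.array([0.0, 0.0, 0.0, 1.5])  # emerges too late for a 3-point fit
        res = growth_rate_analysis(self._series([v, 2 + t], times=t))
        assert np.isnan(res["per_mother"]["g0"]["rates"][0])


# ----- order/scale invariance properties -----

@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_cv_and_slope_scale_and_order_invariant(scale, seed):
    rng = np.random.default_rng(seed)
    mothers = []
    for _ in range(6):
        v = rng.uniform(30, 2000)
        k = int(rng.integers(2, 6))
        buds = rng.uniform(0.05, 0.3, k) * v
        mothers.append((v, buds))
    base = _table(mothers)
    scaled = _table([(v * scale, np.asarray(b) * scale) for v, b in mothers])
    shuffled = _table([mothers[i] for i in rng.permutation(len(mothers))])

    s0, s1 = sibling_cv_stats(base), sibling_cv_stats(scaled)
    assert s1.mean_cv == pytest.approx(s0.mean_cv, rel=1e-9)
    assert sibling_cv_stats(shuffled).mean_cv == pytest.approx(s0.mean_cv, rel=1e-9)
    f0, f1 = summed_fraction_fit(base), summed_fraction_fit(shuffled)
    assert f1["slope"] == pytest.approx(f0["slope"], rel=1e-9)
    assert summed_fraction_fit(scaled)["slope"] == pytest.approx(f0["slope"], rel=1e-6)
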