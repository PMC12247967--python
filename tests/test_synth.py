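"""Synthetic generators: determinism, calibration, and closed-loop recovery."""

import numpy as np
import pytest

from multibud import (
    GeneratorParams,
    gen_bud_volume_table,
    gen_growth_series,
    gen_two_channel_stack,
)
from multibud.budstats import growth_rate_analysis, sibling_cv_stats, summed_fraction_fit
from multibud.imaging import per_bud_cable_signal, subtract_cytosol
from multibud.synth import dirichlet_alpha_for_cv, expected_sibling_cv


def test_same_seed_identical_tables():
    p = GeneratorParams(seed=7, n_mothers=30)
    t1, m1 = gen_bud_volume_table(p)
    t2, m2 = gen_bud_volume_table(p)
    assert t1.mother_ids == t2.mother_ids
    np.testing.assert_array_equal(t1.mother_volumes, t2.mother_volumes)
    for a, b in zip(t1.bud_volumes, t2.bud_volumes):
        np.testing.assert_array_equal(a, b)
    assert m1["seed"] == 7


def test_metadata_sidecar_records_conditions():
    p = GeneratorParams(seed=3, n_mothers=25)
    _, meta = gen_bud_volume_table(p)
    assert meta["n_mothers"] == 25
    assert meta["summed_fraction"] == 0.45
    assert "class_cv_targets" in meta


def test_bud_volumes_sum_to_fraction_without_noise():
    p = GeneratorParams(seed=5, n_mothers=40, total_noise_sd=0.0)
    table, _ = gen_bud_volume_table(p)
    for v, buds in zip(table.mother_volumes, table.bud_volumes):
        assert np.sum(buds) == pytest.approx(0.45 * v, rel=1e-12)


def test_mother_volumes_span_fold_range():
    p = GeneratorParams(seed=9, n_mothers=300)
    table, _ = gen_bud_volume_table(p)
    v = table.mother_volumes
    assert v.max() / v.min() <= 70.0
    assert v.max() / v.min() > 30.0  # most of the configured span is exercised


def test_bud_number_monotone_trend():
    p = GeneratorParams(seed=2, n_mothers=400)
    table, _ = gen_bud_volume_table(p)
    v = table.mother_volumes
    k = np.array([len(b) for b in table.bud_volumes])
    small = k[v < np.quantile(v, 0.25)].mean()
    large = k[v > np.quantile(v, 0.75)].mean()
    assert large > small + 2


def test_three_budded_labels():
    p = GeneratorParams(seed=4, n_mothers=200)
    table, _ = gen_bud_volume_table(p)
    for buds, labs in zip(table.bud_volumes, table.bud_labels):
        if len(buds) == 3:
            assert tuple(sorted(labs)) == ("adjacent", "adjacent", "distant")


def test_dirichlet_calibration_against_monte_carlo():
    """The solved concentration reproduces the target mean sample CV within 1%."""
    for k, target in [(2, 0.12), (3, 0.2), (5, 0.25)]:
        alpha = dirichlet_alpha_for_cv(k, target)
        est = expected_sibling_cv(k, alpha, n_draws=100_000, seed=77)
        assert est == pytest.approx(target, rel=0.01)


def test_infeasible_cv_target_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        dirichlet_alpha_for_cv(2, 1.5)


def test_parameter_recovery_closes_loop():
    """Defaults at n=200, seed 42: estimators recover the generator's targets."""
    p = GeneratorParams(seed=42, n_mothers=200)
    table, _ = gen_bud_volume_table(p)
    fit = summed_fraction_fit(table)
    stats = sibling_cv_stats(table)
    assert fit["slope"] == pytest.approx(0.45, abs=0.02)
    assert stats.mean_cv == pytest.approx(0.20, abs=0.02)
    assert stats.class_mean_cv["2"] == pytest.approx(0.12, abs=0.02)


def test_population_cv_exceeds_sibling_cv():
    p = GeneratorParams(seed=42, n_mothers=200)
    table, _ = gen_bud_volume_table(p)
    stats = sibling_cv_stats(table)
    assert stats.population_cv > stats.mean_cv


class TestGrowthSeries:
    def test_zero_dispersion_identical_trajectories(self):
        p = GeneratorParams(seed=1, growth_rate_cv=0.0, emergence_jitter_min=0.0)
        series, _ = gen_growth_series(p, n_mothers=4)
        res = growth_rate_analysis(series)
        for m in res["per_mother"].values():
            assert m["rate_cv"] == pytest.approx(0.0, abs=1e-9)
        assert not res["any_compensation"]

    def test_persistent_ratio_no_flag(self):
        p = GeneratorParams(seed=1, rate_multipliers=(1.0, 2.0), emergence_jitter_min=0.0)
        series, _ = gen_growth_series(p, n_mothers=5)
        assert not growth_rate_analysis(series)["any_compensation"]

    def test_compensation_flagged(self):
        p = GeneratorParams(
            seed=1, rate_multipliers=(1.0, 2.0), emergence_jitter_min=0.0, compensation=True
        )
        series, _ = gen_growth_series(p, n_mothers=5)
        assert growth_rate_analysis(series)["any_compensation"]


class TestTwoChannelStack:
    def test_default_geometry_and_determinism(self):
        p = GeneratorParams(seed=8, n_frames=3)
        s1, m1, meta = gen_two_channel_stack(p)
        s2, _, _ = gen_two_channel_stack(p)
        assert s1.cable.shape == (3, 17, 40, 40)
        assert s1.voxel_sizes[0] == 0.7
        np.testing.assert_array_equal(s1.cable, s2.cable)
        assert m1.nbud == 3
        assert len(meta["true_amplitudes"]) == 3

    def test_zero_amplitude_corrected_below_noise(self):
        p = GeneratorParams(seed=8, n_frames=4, cable_amplitudes=(0.0, 0.0, 0.0))
        stack, masks, _ = gen_two_channel_stack(p)
        corrected = subtract_cytosol(stack, masks)
        assert corrected[:, masks.cell_mask].mean() < p.image_noise_sd

    def test_injected_ranking_recovered(self):
        """At SNR >= 3 the per-bud signal ranking matches the injected amplitudes
        in at least 95% of frames."""
        p = GeneratorParams(seed=8, n_frames=40, cable_amplitudes=(15.0, 35.0, 60.0))
        stack, masks, meta = gen_two_channel_stack(p)
        signals = per_bud_cable_signal(subtract_cytosol(stack, masks), masks)
        amps = np.asarray(meta["true_amplitudes"])
        matches = [
            (np.argsort(signals[f]) == np.argsort(amps[f])).all()
            for f in range(p.n_frames)
        ]
        assert np.mean(matches) >= 0.95
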