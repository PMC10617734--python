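"""Synthetic cohort generator: determinism, structure, round trips."""
import numpy as np
import pytest

from tidecycle.io_monitor import read_monitor_file
from tidecycle.metrics import modulation_index, segment_amplitudes
from tidecycle.simulate import (
    GroupEffect,
    SimConfig,
    simulate_cohort,
    tide_table,
    write_monitor_fixture,
)


def test_same_config_and_seed_give_bit_identical_cohorts():
    cfg = SimConfig(n_animals=5, rng_seed=11)
    a, truth_a = simulate_cohort(cfg)
    b, truth_b = simulate_cohort(cfg)
    for ra, rb in zip(a, b):
        np.testing.assert_array_equal(ra.counts, rb.counts)
    assert truth_a.equals(truth_b)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(duration_days=0)
    with pytest.raises(ValueError):
        SimConfig(tidal_amplitude=-1)
    with pytest.raises(ValueError):
        SimConfig(arrhythmic_fraction=1.5)


def test_zero_modulation_gives_zero_mean_mi():
    # lunidian_weight = 0: a pure 12.4-h rhythm samples night and day
    # segments symmetrically, so MI is unbiased at M = 0 (the 24.8-h
    # component would beat against the 24-h day/night grid and needs a
    # longer record than 8 days to average out)
    cfg = SimConfig(n_animals=100, modulation_M=0.0, lunidian_weight=0.0,
                    arrhythmic_fraction=0.0, dropout_mean_h=1e9, rng_seed=5)
    records, _ = simulate_cohort(cfg)
    mis = [modulation_index(segment_amplitudes(r)) for r in records]
    assert abs(np.mean([m for m in mis if m is not None])) <= 0.05


def test_mi_strictly_increases_with_modulation():
    means = []
    for M in (0.0, 0.5, 1.0, 2.0):
        cfg = SimConfig(n_animals=60, modulation_M=M, arrhythmic_fraction=0.0,
                        dropout_mean_h=1e9, rng_seed=17)
        records, _ = simulate_cohort(cfg)
        mis = [modulation_index(segment_amplitudes(r)) for r in records]
        means.append(np.mean([m for m in mis if m is not None]))
    assert np.all(np.diff(means) > 0)


def test_expected_totals_scale_with_amplitude_and_duration():
    def mean_total(amplitude, days):
        cfg = SimConfig(n_animals=20, tidal_amplitude=amplitude, baseline_rate=0.0,
                        duration_days=days, arrhythmic_fraction=0.0,
                        dropout_mean_h=1e9, rng_seed=23)
        records, _ = simulate_cohort(cfg)
        return np.mean([r.counts.sum() for r in records])

    base = mean_total(30.0, 4)
    assert mean_total(60.0, 4) == pytest.approx(2 * base, rel=0.05)
    assert mean_total(30.0, 8) == pytest.approx(2 * base, rel=0.05)


def test_arrhythmic_animals_are_flat_at_matched_mean():
    cfg = SimConfig(n_animals=40, arrhythmic_fraction=1.0, dropout_mean_h=1e9,
                    rng_seed=9)
    records, truth = simulate_cohort(cfg)
    assert not truth.rhythmic.any()
    # a flat Poisson series has near-unity Fano factor; the rhythmic rate
    # profile would be strongly overdispersed
    fanos = [r.counts.var() / r.counts.mean() for r in records]
    assert np.median(fanos) < 1.5


def test_group_effects_shift_amplitude_and_period_truth():
    cfg = SimConfig(
        n_animals=4, rng_seed=2,
        group_effects={
            "control": GroupEffect(),
            "kd": GroupEffect(amplitude_mult=0.5, period_shift_h=0.2),
        },
    )
    records, truth = simulate_cohort(cfg)
    assert len(records) == 8
    kd = truth[truth.knockdown == "kd"]
    ctrl = truth[truth.knockdown == "control"]
    assert (kd.amplitude == ctrl.amplitude.iloc[0] * 0.5).all()
    assert kd.period_h.dropna().iloc[0] == pytest.approx(12.6)


def test_dropout_produces_trailing_zeros():
    cfg = SimConfig(n_animals=30, dropout_mean_h=40.0, rng_seed=3)
    records, truth = simulate_cohort(cfg)
    for rec, drop in zip(records, truth.dropout_h):
        if drop < rec.duration_h - 24:
            assert rec.counts[-24:].sum() == 0


class TestMonitorFixture:
    def test_two_animal_round_trip(self, tmp_path):
        cfg = SimConfig(n_animals=2, rng_seed=7)
        records, _ = simulate_cohort(cfg)
        out = write_monitor_fixture(records, tmp_path, tide_tables=tide_table(cfg))
        assert len(out["monitor_files"]) == 1
        back = read_monitor_file(out["monitor_files"][0], out["channel_maps"][0])
        for orig, rt in zip(records, back):
            np.testing.assert_array_equal(orig.counts, rt.counts)
        assert out["tide_csv"].exists()

    def test_forty_animals_split_across_two_files(self, tmp_path):
        records, _ = simulate_cohort(SimConfig(n_animals=40, rng_seed=7))
        out = write_monitor_fixture(records, tmp_path)
        assert len(out["monitor_files"]) == 2

    def test_empty_cohort_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_monitor_fixture([], tmp_path)


def test_tide_table_spans_recording_at_tidal_spacing():
    cfg = SimConfig(rng_seed=0)
    tides = tide_table(cfg)[cfg.collection_id]
    assert tides[0] == pytest.approx(cfg.first_high_tide_ct)
    np.testing.assert_allclose(np.diff(tides), cfg.tidal_period_h)
    assert tides[-1] >= cfg.start_ct + cfg.duration_days * 24
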