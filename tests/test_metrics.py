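"""Segment amplitudes, modulation index, and tidal-time pooling."""
import numpy as np
import pytest

from tidecycle.metrics import (
    SUBJECTIVE_DAY,
    SUBJECTIVE_NIGHT,
    align_to_tide,
    modulation_index,
    phenotype_row,
    segment_amplitudes,
)

from conftest import make_record


def record_from_halfday_peaks(peaks, start_ct=96.0):
    """Build a record whose successive 12-h segments have the given peak
    counts (peak in the middle bin, zeros elsewhere)."""
    counts = np.zeros(24 * len(peaks), dtype=int)
    for i, p in enumerate(peaks):
        counts[24 * i + 12] = p
    return make_record(counts, start_ct=start_ct)


class TestSegmentAmplitudes:
    def test_phases_alternate_and_tile_from_ct_anchor(self):
        # start_ct = 96 → CT 96 mod 24 = 0 → first segment is subjective day
        segs = segment_amplitudes(record_from_halfday_peaks([5, 6, 7, 8])).segments
        assert [s.phase for s in segs] == [SUBJECTIVE_DAY, SUBJECTIVE_NIGHT,
                                           SUBJECTIVE_DAY, SUBJECTIVE_NIGHT]
        assert [s.peak_count for s in segs] == [5, 6, 7, 8]

    def test_night_first_when_record_starts_at_ct12(self):
        segs = segment_amplitudes(record_from_halfday_peaks([5, 6], start_ct=108.0)).segments
        assert [s.phase for s in segs] == [SUBJECTIVE_NIGHT, SUBJECTIVE_DAY]

    def test_all_zero_segment_substituted_to_log_zero(self):
        segs = segment_amplitudes(record_from_halfday_peaks([0, 100])).segments
        assert segs[0].log10_peak == 0.0
        assert segs[1].log10_peak == pytest.approx(2.0)

    def test_adjusted_amplitude_subtracts_the_trough(self):
        counts = np.concatenate([np.full(24, 10), np.full(24, 10)])
        counts[12] = 100
        counts[36] = 100
        segs = segment_amplitudes(make_record(counts, start_ct=96.0)).segments
        assert segs[0].log10_peak == pytest.approx(2.0)
        assert segs[0].log10_adjusted == pytest.approx(np.log10(90), abs=1e-9)

    def test_peak_with_zero_trough(self):
        segs = segment_amplitudes(record_from_halfday_peaks([100])).segments
        assert segs[0].log10_peak == pytest.approx(2.0)
        assert segs[0].log10_adjusted == pytest.approx(2.0)

    def test_partial_segments_dropped_and_cap_respected(self):
        rec = make_record(np.ones(24 * 20 + 7, dtype=int), start_ct=96.0)
        segs = segment_amplitudes(rec).segments
        assert len(segs) == 16  # capped at 8 days
        short = make_record(np.ones(10, dtype=int), start_ct=96.0)
        assert segment_amplitudes(short).segments == []


class TestModulationIndex:
    def test_night_over_day_ratio_of_ten_gives_one(self):
        # day, night, day, night, day with night 100 / day 10
        rec = record_from_halfday_peaks([10, 100, 10, 100, 10])
        assert modulation_index(segment_amplitudes(rec)) == pytest.approx(1.0)

    def test_symmetric_activity_gives_zero(self):
        rec = record_from_halfday_peaks([50, 50, 50, 50])
        assert modulation_index(segment_amplitudes(rec)) == pytest.approx(0.0)

    def test_zero_substitution_composes_with_pairing(self):
        # night peak 100 followed by an all-zero day → 2.0 − 0 = 2.0
        rec = record_from_halfday_peaks([10, 100, 0], start_ct=96.0)
        assert modulation_index(segment_amplitudes(rec)) == pytest.approx(2.0)

    def test_no_complete_pair_is_undefined(self):
        rec = record_from_halfday_peaks([10])  # lone day segment
        assert modulation_index(segment_amplitudes(rec)) is None

    def test_scaling_counts_shifts_amplitudes_but_not_mi(self):
        rec = record_from_halfday_peaks([10, 100, 20, 200])
        scaled = rec.replace_counts(rec.counts * 10)
        a, b = segment_amplitudes(rec), segment_amplitudes(scaled)
        for s, t in zip(a.segments, b.segments):
            assert t.log10_peak == pytest.approx(s.log10_peak + 1.0)
        assert modulation_index(b) == pytest.approx(modulation_index(a))


def test_phenotype_row_overall_is_weighted_mean_of_phases():
    rec = record_from_halfday_peaks([10, 100, 20, 200, 30])
    row = phenotype_row(rec)
    segs = segment_amplitudes(rec).segments
    n_night = sum(s.phase == SUBJECTIVE_NIGHT for s in segs)
    n_day = len(segs) - n_night
    expected = (row["amp_night"] * n_night + row["amp_day"] * n_day) / len(segs)
    assert row["amp_overall"] == pytest.approx(expected)
    assert row["MI"] is not None


class TestAlignToTide:
    def test_single_record_identity(self):
        rec = make_record(np.arange(100) % 7, start_ct=96.0)
        tides = {"c0": np.array([96.0, 108.4, 120.8, 133.2])}
        pooled = align_to_tide([rec], tides)
        np.testing.assert_allclose(pooled["mean_count"], rec.counts)

    def test_records_offset_by_one_tidal_period_superpose(self):
        # a 12.5-h rhythm is commensurate with the 0.5-h bins (25 bins/cycle),
        # so a one-cycle offset is exactly representable
        t = np.arange(0, 400) * 0.5
        wave = np.round(50 + 40 * np.cos(2 * np.pi * t / 12.5)).astype(int)
        r1 = make_record(wave[:300], start_ct=96.0)
        r2 = make_record(wave[25 : 25 + 300], start_ct=96.0)
        tides = {"c0": np.arange(96.0, 300.0, 12.5)}
        pooled = align_to_tide([r1, r2], tides)
        solo = align_to_tide([r1], tides)
        n = min(len(pooled), len(solo))
        np.testing.assert_allclose(pooled["mean_count"][:n], solo["mean_count"][:n])

    def test_opposite_phase_records_align_constructively(self):
        t = np.arange(0, 384) * 0.5
        w1 = np.round(50 + 40 * np.cos(2 * np.pi * t / 12.4)).astype(int)
        w2 = np.round(50 + 40 * np.cos(2 * np.pi * t / 12.4 + np.pi)).astype(int)
        r1 = make_record(w1, start_ct=96.0, collection_id="cA")
        r2 = make_record(w2, start_ct=96.0, collection_id="cB")
        tides = {
            "cA": np.arange(96.0, 300.0, 12.4),          # high tide at peak of r1
            "cB": np.arange(96.0 + 6.2, 300.0, 12.4),    # half a cycle later
        }
        aligned = align_to_tide([r1, r2], tides)
        naive = (r1.counts + r2.counts) / 2.0
        # unaligned averaging cancels the rhythm; tidal alignment preserves it
        assert np.ptp(naive[:200]) < 25
        assert np.ptp(aligned["mean_count"][:200].to_numpy()) > 60

    def test_missing_tide_table_is_a_lookup_error(self):
        rec = make_record(np.ones(50, dtype=int), collection_id="cX")
        with pytest.raises(KeyError):
            align_to_tide([rec], {"other": np.array([96.0])})
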