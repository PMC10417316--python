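"""Preprocessing chain: QC, wavelet bands, segmentation, resampling, labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppgbp import (
    InvalidArgumentError,
    LabelExtractionError,
    StandardizationError,
    bp_range_filter,
    detect_systolic_peaks,
    dwt_decompose,
    dwt_denoise,
    dwt_reconstruct,
    extract_bp_labels,
    flat_region_qc,
    ground_truth_for_span,
    record_to_segments,
    segment_two_cycle,
    spline_resample,
    subband_frequency_ranges,
    zscore_standardize,
)
from ppgbp.preprocessing import (
    read_segments_npz,
    read_segments_text,
    write_segments_npz,
    write_segments_text,
)

FS = 125.0


def sine(freq, duration=10.0, fs=FS, amplitude=1.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestFlatRegionQC:
    def test_pure_sine_passes(self):
        report = flat_region_qc(sine(1.0), FS, min_flat_duration=1.0)
        assert report.passed
        assert report.flatline_spans == [] and report.flatpeak_spans == []

    def test_constant_insert_is_a_flatline(self):
        x = sine(1.0)
        x[250:500] = x[250]  # 2 s constant
        report = flat_region_qc(x, FS, min_flat_duration=1.0, slope_tolerance=0.0)
        assert not report.passed
        assert len(report.flatline_spans) == 1
        start, stop = report.flatline_spans[0]
        assert start <= 250 and stop >= 500

    def test_clipped_peak_is_a_flatpeak(self):
        x = sine(1.0)
        # clip one crest into a 5-sample plateau: everything on the crest
        # above the value 2 samples out is saturated, as amplitude clipping does
        crest = np.argmax(x[200:400]) + 200
        x[crest - 2 : crest + 3] = x[crest - 2]
        report = flat_region_qc(x, FS, min_flat_duration=1.0)
        spans = report.flatpeak_spans
        assert len(spans) == 1
        # run-length oracle over the difference sequence
        diff = np.diff(x)
        start, stop = spans[0]
        assert np.all(diff[start : stop - 1] == 0)
        assert stop - start == 5

    def test_empty_signal_rejected(self):
        with pytest.raises(InvalidArgumentError):
            flat_region_qc([], FS)


class TestSubbandRanges:
    def test_eight_levels_give_nine_bands_partitioning_nyquist(self):
        bands = subband_frequency_ranges(125.0, 8)
        assert len(bands) == 9
        edges = sorted({low for _, low, _ in bands} | {high for _, _, high in bands})
        assert edges[0] == 0.0 and edges[-1] == 62.5
        # bands tile [0, Nyquist] without gaps or overlaps
        spans = sorted((low, high) for _, low, high in bands)
        for (l1, h1), (l2, h2) in zip(spans, spans[1:]):
            assert h1 == pytest.approx(l2)

    def test_first_detail_and_deep_approximation_edges(self):
        bands = dict((name, (low, high)) for name, low, high in subband_frequency_ranges(125.0, 8))
        assert bands["D1"] == (pytest.approx(31.25), pytest.approx(62.5))
        assert bands["A8"] == (0.0, pytest.approx(125 / 512))


class TestDWT:
    def test_round_trip_identity(self, rng):
        x = rng.normal(size=4096)
        bands = dwt_decompose(x, "db4", 8)
        assert bands.band_count() == 9
        back = dwt_reconstruct(bands)
        assert np.max(np.abs(back - x)) < 1e-8 * np.max(np.abs(x))

    def test_zero_signal_gives_zero_bands(self):
        bands = dwt_decompose(np.zeros(2048), "db4", 8)
        assert np.all(bands.approximation == 0)
        assert all(np.all(d == 0) for d in bands.details)

    def test_too_short_signal_rejected(self):
        with pytest.raises(InvalidArgumentError):
            dwt_decompose(np.ones(100), "db4", 8)

    def test_full_length_record_decomposes_into_nine_bands(self):
        x = np.sin(np.arange(37_500) * 0.05)
        assert dwt_decompose(x, "db4", 8).band_count() == 9


class TestDenoise:
    def test_baseline_band_removed(self):
        x = sine(0.05, duration=60.0)
        out = dwt_denoise(x, FS)
        assert np.max(np.abs(out)) < 0.05

    def test_cardiac_band_retained(self):
        x = sine(2.0, duration=20.0)
        out = dwt_denoise(x, FS)
        r = np.corrcoef(x, out)[0, 1]
        assert r > 0.99

    def test_high_frequency_tone_attenuated(self, clean_record):
        tone = sine(40.0, duration=len(clean_record) / FS, amplitude=0.2)
        noisy = clean_record.ppg + tone
        out = dwt_denoise(noisy, FS)
        # power of the 40 Hz line before and after, via the spectrum bin
        spectrum = np.abs(np.fft.rfft(out - dwt_denoise(clean_record.ppg, FS)))
        freqs = np.fft.rfftfreq(len(out), 1 / FS)
        bin40 = np.argmin(np.abs(freqs - 40.0))
        in_power = np.abs(np.fft.rfft(tone))[bin40]
        assert 20 * np.log10(in_power / max(spectrum[bin40], 1e-12)) > 20


class TestPeakDetection:
    def test_peak_count_and_spacing_on_fixed_rate_record(self):
        from ppgbp import SyntheticConfig, synth_record

        record = synth_record(
            SyntheticConfig(
                duration=10.0,
                heart_rate_range=(59.9, 60.1),
                hr_variability=0.0,
                noise_sd=0.0,
                abp_noise_sd=0.0,
                drift_amplitude=0.0,
                seed=2,
            )
        )
        peaks = detect_systolic_peaks(record.ppg, FS)
        assert abs(len(peaks) - 10) <= 1
        assert np.all(np.abs(np.diff(peaks) - 125) <= 2)

    def test_constant_signal_yields_nothing(self):
        assert detect_systolic_peaks(np.ones(1000), FS).size == 0

    def test_two_sinusoid_periods_give_two_peaks(self):
        x = sine(1.0, duration=2.0)
        peaks = detect_systolic_peaks(x, FS)
        assert len(peaks) == 2
        np.testing.assert_allclose(peaks, [31, 156], atol=1)


class TestSegmentation:
    def test_definition_example(self):
        spans = segment_two_cycle(None, [100, 225, 350, 475, 600])
        assert spans == [(100, 350), (225, 475), (350, 600)]

    @pytest.mark.parametrize("n_peaks,expected", [(3, 1), (2, 0), (1, 0), (0, 0)])
    def test_span_count_is_peaks_minus_two(self, n_peaks, expected):
        peaks = list(range(0, n_peaks * 100, 100))
        assert len(segment_two_cycle(None, peaks)) == expected

    @given(st.lists(st.integers(0, 10_000), min_size=0, max_size=40, unique=True))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_brute_force_enumeration(self, peaks):
        peaks = sorted(peaks)
        brute = [(peaks[i], peaks[i + 2]) for i in range(max(0, len(peaks) - 2))]
        assert segment_two_cycle(None, peaks) == brute


class TestSplineResample:
    def test_output_has_exactly_target_length(self, rng):
        for n in (50, 137, 200, 353):
            assert len(spline_resample(rng.normal(size=n))) == 200

    def test_identity_on_length_200_input(self, rng):
        x = rng.normal(size=200)
        np.testing.assert_allclose(spline_resample(x), x, atol=1e-9)

    def test_linear_ramp_reproduced(self):
        ramp = np.linspace(0.0, 5.0, 50)
        out = spline_resample(ramp)
        np.testing.assert_allclose(out, np.linspace(0.0, 5.0, 200), atol=1e-9)

    def test_endpoints_preserved(self, rng):
        x = rng.normal(size=77)
        out = spline_resample(x)
        assert out[0] == pytest.approx(x[0], abs=1e-9)
        assert out[-1] == pytest.approx(x[-1], abs=1e-9)

    def test_short_excerpt_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spline_resample([1.0, 2.0, 3.0])


class TestLabels:
    def test_single_beat_labels(self, clean_record):
        peak, sbp, dbp = clean_record.beats[2]
        nxt = clean_record.beats[3][0]
        prev = clean_record.beats[1][0]
        got = extract_bp_labels(clean_record.abp, (prev, nxt), FS)
        assert got[0] == pytest.approx(sbp, abs=1.0)
        assert got[1] == pytest.approx(dbp, abs=1.6)

    def test_constant_abp_raises(self):
        with pytest.raises(LabelExtractionError):
            extract_bp_labels(np.full(500, 80.0), (0, 500), FS)

    def test_two_beat_span_averages(self):
        # synthetic two-beat ABP built directly from known pressures
        from ppgbp.synthetic import synth_pulse

        beats = [(120.0, 80.0), (122.0, 82.0)]
        parts = []
        for sbp, dbp in beats + [(121.0, 81.0)]:
            pulse = synth_pulse(125, 1.0, 0.3, 0.6)
            parts.append(dbp + (sbp - dbp) * pulse / pulse.max())
        abp = np.concatenate(parts)
        got = extract_bp_labels(abp, (40, 40 + 250), FS)
        assert got[0] == pytest.approx(121.0, abs=1.0)
        assert got[1] == pytest.approx(81.0, abs=1.0)


class TestBPRangeFilter:
    @pytest.mark.parametrize(
        "sbp,dbp,keep",
        [
            (150.0, 70.0, True),
            (200.0, 70.0, False),
            (150.0, 120.0, False),
            (80.0, 60.0, False),
            (150.0, 40.0, False),
        ],
    )
    def test_printed_inequalities(self, sbp, dbp, keep):
        assert bp_range_filter((sbp, dbp)) is keep

    def test_boundary_grid_matches_rule_exactly(self):
        for sbp in (79.0, 80.0, 81.0, 199.0, 200.0, 201.0):
            for dbp in (39.0, 40.0, 41.0, 119.0, 120.0, 121.0):
                expected = not (sbp >= 200 or dbp >= 120 or sbp <= 80 or dbp <= 40)
                assert bp_range_filter((sbp, dbp)) is expected


class TestStandardization:
    def test_three_point_worked_example(self):
        out = zscore_standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [-1.22474487, 0.0, 1.22474487], atol=1e-6)

    def test_idempotent_and_population_sd(self, rng):
        x = rng.normal(2.0, 3.0, size=200)
        z = zscore_standardize(x)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(zscore_standardize(z), z, atol=1e-9)

    def test_constant_segment_raises(self):
        with pytest.raises(StandardizationError):
            zscore_standardize(np.full(200, 3.0))


class TestEndToEnd:
    def test_clean_record_labels_match_ground_truth(self, clean_record):
        segments = record_to_segments(clean_record)
        assert len(segments) > 20
        for seg in segments:
            true_sbp, true_dbp = ground_truth_for_span(clean_record, *seg.span)
            assert seg.sbp == pytest.approx(true_sbp, abs=2.0)
            assert seg.dbp == pytest.approx(true_dbp, abs=2.0)
            assert len(seg.values) == 200
            assert seg.values.mean() == pytest.approx(0.0, abs=1e-6)
            assert seg.values.std(ddof=0) == pytest.approx(1.0, abs=1e-6)

    def test_corrupted_record_rejected_entirely(self):
        from ppgbp import SyntheticConfig, synth_record

        record = synth_record(SyntheticConfig(duration=30.0, flatline_prob=1.0, seed=6))
        assert record_to_segments(record) == []


class TestSegmentContainers:
    def test_text_and_npz_round_trips(self, tmp_path, small_segments):
        assert small_segments, "fixture must yield segments"
        tpath = tmp_path / "segments.tsv"
        write_segments_text(small_segments, tpath)
        back = read_segments_text(tpath)
        npath = tmp_path / "segments.npz"
        write_segments_npz(small_segments, npath)
        back2 = read_segments_npz(str(npath) if str(npath).endswith(".npz") else npath)
        for restored in (back, back2):
            assert len(restored) == len(small_segments)
            for a, b in zip(restored, small_segments):
                np.testing.assert_array_equal(a.values, b.values)
                assert (a.sbp, a.dbp) == (b.sbp, b.dbp)
                assert a.subject_id == b.subject_id
                assert a.span == b.span and a.peak_indices == b.peak_indices
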