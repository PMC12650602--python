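"""The denoise -> downsample -> segment -> z-score chain."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hctgnet import (EXCLUDED, EcgRecord, denoise, preprocess_record,
                     resample_signal, rescale_annotation, segment_beats,
                     zscore)
from hctgnet.preprocess import (SEGMENT_LENGTH, BeatDataset, PreprocessConfig,
                                normalization_params)
from hctgnet.synth import default_morphologies, generate_beat, generate_record


def _tone(freq, fs=360.0, seconds=30.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestDenoise:
    def test_baseline_wander_strongly_attenuated(self):
        """A 0.2 Hz drift component loses at least 20 dB."""
        x = _tone(0.2)
        y = denoise(x, 360)
        assert _rms(y[3600:-3600]) < 0.1 * _rms(x)

    def test_passband_tone_preserved(self):
        x = _tone(10.0)
        y = denoise(x, 360)
        assert abs(_rms(y[3600:-3600]) / _rms(x[3600:-3600]) - 1) < 0.11

    @pytest.mark.parametrize("freq", [1.0, 5.0, 20.0, 35.0])
    def test_passband_edges_within_1db(self, freq):
        x = _tone(freq)
        y = denoise(x, 360)
        core = slice(3600, -3600)
        gain_db = 20 * np.log10(_rms(y[core]) / _rms(x[core]))
        assert gain_db > -1.0

    def test_zero_phase_keeps_r_peak_position(self):
        beat = generate_beat(default_morphologies()["N"], fs=360, rng_seed=0)
        pad = np.zeros(720)
        clean = np.concatenate([pad, beat, pad])
        wander = 0.3 * np.sin(2 * np.pi * 0.3 * np.arange(len(clean)) / 360)
        filtered = denoise(clean + wander, 360)
        assert abs(int(np.argmax(filtered)) - int(np.argmax(clean))) <= 1

    def test_output_length_unchanged(self):
        x = np.random.default_rng(0).standard_normal(4321)
        assert len(denoise(x, 360)) == 4321

    def test_short_signal_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="720"):
            denoise(np.zeros(100), 360)


class TestResample:
    def test_length_mapping(self):
        y, scale = resample_signal(np.zeros(3600), 360, 125)
        assert len(y) == 1250
        assert scale == Fraction(125, 360)

    def test_tone_frequency_and_amplitude_preserved(self):
        x = _tone(5.0, fs=360, seconds=20)
        y, _ = resample_signal(x, 360, 125)
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(len(y), d=1 / 125)
        peak = freqs[np.argmax(spec)]
        assert abs(peak - 5.0) < 0.1
        core = y[250:-250]
        assert abs(core.max() - 1.0) < 0.02

    def test_constant_signal_maps_to_constant(self):
        y, _ = resample_signal(np.full(720, 2.5), 360, 125)
        assert len(y) == 250
        # constant up to the anti-aliasing filter's design ripple
        np.testing.assert_allclose(y, 2.5, atol=1e-4)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="[Uu]psampl"):
            resample_signal(np.zeros(100), 125, 360)

    @pytest.mark.parametrize("idx360,expected", [
        (360, 125), (0, 0), (1000, 347)])
    def test_annotation_rescaling(self, idx360, expected):
        assert rescale_annotation(idx360, Fraction(125, 360)) == expected


class TestZscore:
    def test_constant_window_maps_to_zero(self):
        np.testing.assert_array_equal(zscore([5.0, 5.0, 5.0, 5.0]),
                                      np.zeros(4))

    def test_matches_direct_mean_sd_arithmetic(self):
        # mu = 0, population sigma = sqrt(2/3)
        out = zscore([-1.0, 0.0, 1.0])
        np.testing.assert_allclose(out, [-1.224744, 0.0, 1.224744], atol=1e-4)

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=50))
    def test_output_mean_zero_and_idempotent(self, values):
        x = np.asarray(values)
        z = zscore(x)
        assert abs(z.mean()) < 1e-9
        if x.std() > 1e-3:  # idempotence up to the epsilon guard
            np.testing.assert_allclose(zscore(z), z, atol=1e-4)

    def test_params_expose_window_statistics(self):
        p = normalization_params([1.0, 3.0])
        assert p.mu == 2.0 and p.sigma == 1.0 and p.epsilon == 1e-6


class TestSegmentation:
    def test_window_geometry(self):
        signal = np.arange(1250.0)
        segs, skips = segment_beats(signal, [(600, "N")])
        assert len(segs) == 1
        seg = segs[0]
        assert len(seg.values) == SEGMENT_LENGTH
        assert seg.values[0] == 510.0          # r - 90
        assert seg.values[90] == 600.0         # R sample at offset 90
        assert seg.values[-1] == 697.0         # half-open end at r + 98
        assert skips == {"skipped_boundary": 0, "skipped_excluded": 0}

    def test_insufficient_left_context_skipped(self):
        segs, skips = segment_beats(np.zeros(1250), [(80, "N")])
        assert segs == []
        assert skips["skipped_boundary"] == 1

    def test_excluded_annotations_dropped_not_counted_as_beats(self):
        anns = [(300, "N"), (450, EXCLUDED), (600, "V"), (900, "F")]
        segs, skips = segment_beats(np.zeros(1250), anns)
        assert [s.label for s in segs] == ["N", "V", "F"]
        assert skips["skipped_excluded"] == 1

    @given(st.lists(st.integers(0, 2000), max_size=20))
    def test_never_reads_outside_signal(self, positions):
        signal = np.arange(1500.0)
        anns = sorted({(p, "N") for p in positions})
        segs, _skips = segment_beats(signal, anns)
        for seg in segs:
            assert 90 <= seg.r_index_125 <= len(signal) - 98
            assert len(seg.values) == SEGMENT_LENGTH


class TestFullChain:
    def test_single_class_record_counts_and_labels(self):
        rec = generate_record(70, (1, 0, 0, 0, 0), fs=360, rng_seed=4)
        ds = preprocess_record(rec)
        # every interior annotation has context by construction
        assert len(ds) >= len(rec.annotations) - 2
        assert set(ds.labels) == {"N"}
        assert ds.beats.shape[1] == SEGMENT_LENGTH

    def test_segment_labels_match_generating_classes(self, synth_record):
        ds = preprocess_record(synth_record)
        from hctgnet.wfdb_io import AAMI_MAP

        true_labels = [AAMI_MAP[s] for _i, s in synth_record.annotations]
        # boundary beats may be dropped; remaining labels must align in order
        assert len(ds) >= len(true_labels) - 2
        segment_step = [p for p in ds.provenance if p["step"] == "segment"][0]
        assert segment_step["skipped_boundary"] + len(ds) == len(true_labels)

    def test_rows_are_normalised(self, synth_record):
        ds = preprocess_record(synth_record)
        np.testing.assert_allclose(ds.beats.mean(axis=1), 0, atol=1e-6)
        np.testing.assert_allclose(ds.beats.std(axis=1), 1, atol=1e-3)

    def test_empty_annotations_give_empty_dataset(self):
        rec = EcgRecord(samples=np.random.default_rng(0).standard_normal(7200),
                        fs=360, lead_name="MLII", annotations=[],
                        record_id="empty")
        ds = preprocess_record(rec)
        assert len(ds) == 0

    def test_wrong_rate_rejected(self):
        rec = EcgRecord(samples=np.zeros(1000), fs=250, lead_name="MLII",
                        annotations=[], record_id="odd")
        with pytest.raises(ValueError, match="250"):
            preprocess_record(rec)

    def test_stage_errors_name_the_stage(self):
        rec = EcgRecord(samples=np.zeros(100), fs=360, lead_name="MLII",
                        annotations=[], record_id="short")
        with pytest.raises(RuntimeError, match="denoise"):
            preprocess_record(rec)

    def test_provenance_records_every_stage(self, synth_record):
        ds = preprocess_record(synth_record)
        steps = [p["step"] for p in ds.provenance]
        assert steps == ["source", "denoise", "resample", "segment",
                         "normalize"]

    def test_npz_roundtrip(self, tmp_path, synth_record):
        ds = preprocess_record(synth_record)
        ds.to_npz(tmp_path / "ds.npz")
        back = BeatDataset.from_npz(tmp_path / "ds.npz")
        np.testing.assert_array_equal(back.beats, ds.beats)
        np.testing.assert_array_equal(back.labels, ds.labels)
        assert back.provenance == ds.provenance
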