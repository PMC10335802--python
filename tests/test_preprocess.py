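import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegloop.errors import FilterStateError, InvalidArgumentError
from eegloop.preprocess import (
    Epoch,
    EpochSpec,
    FilterSpec,
    apply_causal,
    baseline_correct,
    design_filter,
    epoch_rolling,
    epoch_timelocked,
    filter_gain,
    group_delay,
    narrowband_power,
    notch_spec,
)
from eegloop.streams import MarkerEvent, SampleBlock

FS = 256.0


def block_from(values, fs=FS, t0=0.0):
    values = np.atleast_2d(values.T).T if values.ndim == 1 else values
    return SampleBlock(t0 + np.arange(len(values)) / fs, values)


class TestDesignFilter:
    def test_default_bandpass_gains(self):
        """8-30 Hz, 129 taps at 256 Hz: passes 15 Hz, rejects 50 Hz by >=20 dB
        (frequency-response oracle: DTFT of the taps)."""
        taps = design_filter(FilterSpec("bandpass", (8, 30), order=129), FS)
        assert filter_gain(taps, 15.0, FS) >= 0.9
        assert filter_gain(taps, 50.0, FS) <= 0.1

    def test_notch_gains(self):
        taps = design_filter(notch_spec(50.0, bw=4.0, order=513), FS)
        assert filter_gain(taps, 50.0, FS) <= 0.05
        assert filter_gain(taps, 40.0, FS) >= 0.9

    def test_group_delay_formula(self):
        spec = FilterSpec("lowpass", (40.0,), order=129)
        assert group_delay(spec, FS) == pytest.approx((129 - 1) / (2 * FS))

    def test_edge_at_nyquist_rejected(self):
        with pytest.raises(InvalidArgumentError):
            design_filter(FilterSpec("lowpass", (128.0,), order=9), FS)

    def test_even_order_rejected(self):
        with pytest.raises(InvalidArgumentError):
            FilterSpec("lowpass", (40.0,), order=10)

    def test_linear_phase_symmetric_taps(self):
        taps = design_filter(FilterSpec("bandpass", (8, 30), order=65), FS)
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-12)


class TestApplyCausal:
    def test_impulse_response_is_causal(self, rng):
        x = np.zeros((200, 1))
        x[60, 0] = 1.0
        taps = design_filter(FilterSpec("bandpass", (8, 30), order=65), FS)
        out, _ = apply_causal(taps, block_from(x))
        assert np.all(out.values[:60] == 0.0)
        assert np.any(out.values[60:] != 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_specs_are_causal(self, seed):
        """Impulse test across random FIR specs: output never precedes input."""
        rng = np.random.default_rng(seed)
        kind = rng.choice(["bandpass", "highpass", "lowpass", "notch"])
        order = int(rng.choice([33, 65, 129]))
        if kind in ("bandpass", "notch"):
            lo = rng.uniform(2, 40)
            spec = FilterSpec(kind, (lo, lo + rng.uniform(5, 40)), order=order)
        else:
            spec = FilterSpec(kind, (rng.uniform(2, 80),), order=order)
        taps = design_filter(spec, FS)
        x = np.zeros((3 * order, 1))
        pos = order
        x[pos, 0] = 1.0
        out, _ = apply_causal(taps, block_from(x))
        assert np.all(out.values[:pos] == 0.0)

    def test_chunked_equals_batch(self, rng):
        taps = design_filter(FilterSpec("bandpass", (8, 30), order=129), FS)
        signal = rng.standard_normal((int(10 * FS), 3))
        full = block_from(signal)
        batch, _ = apply_causal(taps, full)
        state = None
        outs = []
        for start in range(0, full.n_samples, int(FS)):
            chunk = SampleBlock(full.timestamps[start:start + int(FS)],
                                signal[start:start + int(FS)])
            out, state = apply_causal(taps, chunk, state)
            outs.append(out.values)
        np.testing.assert_allclose(np.concatenate(outs), batch.values, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.integers(1, 400), min_size=1, max_size=8))
    def test_chunked_equals_batch_any_chunking(self, chunk_sizes):
        rng = np.random.default_rng(0)
        taps = design_filter(FilterSpec("highpass", (1.0,), order=65), FS)
        n = sum(chunk_sizes)
        signal = rng.standard_normal((n, 2))
        batch, _ = apply_causal(taps, block_from(signal))
        state = None
        outs, start = [], 0
        for size in chunk_sizes:
            chunk = SampleBlock(np.arange(start, start + size) / FS,
                                signal[start:start + size])
            out, state = apply_causal(taps, chunk, state)
            outs.append(out.values)
            start += size
        np.testing.assert_allclose(np.concatenate(outs), batch.values, atol=1e-12)

    def test_zero_in_zero_out(self):
        taps = design_filter(FilterSpec("lowpass", (40.0,), order=33), FS)
        out, _ = apply_causal(taps, block_from(np.zeros((100, 2))))
        assert np.all(out.values == 0.0)

    def test_channel_change_mid_stream_rejected(self, rng):
        taps = design_filter(FilterSpec("lowpass", (40.0,), order=33), FS)
        _, state = apply_causal(taps, block_from(rng.standard_normal((50, 2))))
        with pytest.raises(FilterStateError):
            apply_causal(taps, block_from(rng.standard_normal((50, 3))), state)


class TestEpochTimelocked:
    def test_window_arithmetic(self, rng):
        block = block_from(rng.standard_normal((int(3 * FS), 2)))
        spec = EpochSpec(-0.2, 0.8)
        epochs, skips = epoch_timelocked(block, [MarkerEvent(1.0, {})], spec)
        assert not skips
        (ep,) = epochs
        assert ep.n_samples == 256
        # first sample at-or-after onset + t_min = 0.8 s
        assert abs(block.timestamps[ep.meta["start_index"]] - 0.8) < 1 / FS

    def test_marker_near_stream_end_skipped(self, rng):
        block = block_from(rng.standard_normal((int(1 * FS), 2)))
        epochs, skips = epoch_timelocked(block, [MarkerEvent(0.9, {})],
                                         EpochSpec(0.0, 0.8))
        assert epochs == []
        assert skips[0][1] == "insufficient data"

    def test_count_conservation(self, rng):
        block = block_from(rng.standard_normal((int(5 * FS), 2)))
        markers = [MarkerEvent(t, {}) for t in np.linspace(-1, 6, 40)]
        epochs, skips = epoch_timelocked(block, markers, EpochSpec(-0.1, 0.4))
        assert len(epochs) + len(skips) == len(markers)

    def test_label_copied_from_marker(self, rng):
        block = block_from(rng.standard_normal((int(2 * FS), 2)))
        markers = [MarkerEvent(0.5, {"label": "left"}), MarkerEvent(1.0, {})]
        epochs, _ = epoch_timelocked(block, markers, EpochSpec(0.0, 0.5))
        assert epochs[0].label == "left"
        assert epochs[1].label is None

    def test_alignment_against_synth_truth(self):
        """Epochs align to within 1 sample of the generator's truth."""
        from eegloop.synth import SynthConfig, make_oddball_session

        config = SynthConfig(seed=3, erp_amp=0.0)
        session = make_oddball_session(4, 100, 0.4, 0, config)
        epochs, skips = epoch_timelocked(session.eeg, session.markers,
                                         EpochSpec(0.0, 0.3), fs=config.fs)
        assert not skips
        for ep, marker in zip(epochs, session.markers):
            start_ts = session.eeg.timestamps[ep.meta["start_index"]]
            assert abs(start_ts - marker.timestamp) < 1 / config.fs


class TestEpochRolling:
    def test_counting_formula(self, rng):
        block = block_from(rng.standard_normal((int(10 * FS), 1)))
        epochs = epoch_rolling(block, 1.0, 0.5)
        assert len(epochs) == 19

    def test_nonoverlapping_tiling(self, rng):
        block = block_from(rng.standard_normal((int(4 * FS), 1)))
        epochs = epoch_rolling(block, 1.0, 1.0)
        assert len(epochs) == 4
        starts = [ep.meta["start_index"] for ep in epochs]
        assert starts == [0, 256, 512, 768]

    def test_too_short_block_gives_empty(self, rng):
        block = block_from(rng.standard_normal((100, 1)))
        assert epoch_rolling(block, 10.0, 1.0) == []

    def test_labels_absent(self, rng):
        block = block_from(rng.standard_normal((int(2 * FS), 1)))
        assert all(ep.label is None for ep in epoch_rolling(block, 0.5, 0.25))

    @settings(max_examples=40, deadline=None)
    @given(
        n_seconds=st.floats(0.5, 8.0),
        length=st.floats(0.1, 3.0),
        step=st.floats(0.05, 2.0),
    )
    def test_count_matches_enumeration(self, n_seconds, length, step):
        """Oracle: brute-force enumeration of window start indices."""
        rng = np.random.default_rng(1)
        n = int(n_seconds * FS)
        block = block_from(rng.standard_normal((n, 1)))
        epochs = epoch_rolling(block, length, step)
        n_len = int(round(length * FS))
        n_step = max(1, int(round(step * FS)))
        if n_len < 2 or n_len > n:
            expected = 0
        else:
            expected = len(range(0, n - n_len + 1, n_step))
        assert len(epochs) == expected


class TestBaseline:
    def epoch_of(self, data):
        return Epoch(0.0, data, meta={"fs": FS, "t_min": -0.2})

    def test_constant_channel_zeroed(self):
        ep = self.epoch_of(np.full((1, 128), 7.0))
        out = baseline_correct(ep, (-0.2, 0.0))
        assert np.all(out.data == 0.0)

    def test_baseline_window_mean_is_zero(self, rng):
        ep = self.epoch_of(rng.standard_normal((4, 256)))
        out = baseline_correct(ep, (-0.2, 0.0))
        window = out.data[:, :51]
        assert np.all(np.abs(window.mean(axis=1)) <= 1e-12)

    def test_idempotent(self, rng):
        ep = self.epoch_of(rng.standard_normal((3, 256)))
        once = baseline_correct(ep, (-0.2, 0.1))
        twice = baseline_correct(once, (-0.2, 0.1))
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_sine_shape_preserved(self):
        t = np.arange(256) / FS
        sine = np.sin(2 * np.pi * 10 * t)
        ep = self.epoch_of((sine + 5.0)[None, :])
        out = baseline_correct(ep, (-0.2, 0.8))
        corr = np.corrcoef(out.data[0], sine)[0, 1]
        assert corr >= 0.999

    def test_empty_window_rejected(self, rng):
        ep = self.epoch_of(rng.standard_normal((2, 128)))
        with pytest.raises(InvalidArgumentError):
            baseline_correct(ep, (0.5, 0.5))


class TestNarrowbandPower:
    def test_zero_signal_zero_power(self):
        block = block_from(np.zeros((int(4 * FS), 2)))
        assert np.all(narrowband_power(block, 50.0) == 0.0)

    def test_quadratic_scaling(self):
        t = np.arange(int(8 * FS)) / FS
        p = []
        for amp in (1.0, 2.0):
            x = amp * np.sin(2 * np.pi * 50 * t)
            p.append(narrowband_power(block_from(x[:, None]), 50.0)[0])
        assert p[1] / p[0] == pytest.approx(4.0, rel=0.05)

    def test_ranking_matches_line_amplitude(self):
        t = np.arange(int(8 * FS)) / FS
        x = np.stack([1.0 * np.sin(2 * np.pi * 50 * t),
                      3.0 * np.sin(2 * np.pi * 50 * t)], axis=1)
        power = narrowband_power(block_from(x), 50.0)
        assert power[1] > power[0]

    def test_band_below_one_hz_rejected(self, white_block):
        with pytest.raises(InvalidArgumentError):
            narrowband_power(white_block, 2.0, bw=4.0)
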