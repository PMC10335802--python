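"""Seeded synthetic EEG: background noise, oddball / motor-imagery / tap sessions.

Every generator is a pure function of ``(config, arguments)``: the same
seed and config give bit-identical output.  Each session carries a
``truth`` record (hidden target class, true stimulus latency, per-epoch
labels, artifact times) sufficient to score any downstream estimate
without re-deriving anything.

Background model: per-channel ``1/f^alpha`` noise, synthesized by spectral
shaping of white Gaussian noise and normalized to unit standard deviation,
plus a line-frequency sinusoid with a per-channel phase and optional
low-frequency blink transients weighted toward the frontal (first)
channels.  Amplitude parameters are therefore expressed relative to a
unit-variance background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import InvalidArgumentError
from .preprocess import FilterSpec, design_filter
from .streams import MarkerEvent, SampleBlock, StreamInfo


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic EEG source.

    ``hw_latency`` is the hidden stimulus-to-EEG delay: every evoked
    response lands ``hw_latency`` later than the marker timestamp claims,
    emulating the 20-40 ms delays of consumer wireless EEG hardware.
    ``marker_jitter_sd`` additionally jitters each evoked response around
    its nominal time.
    """

    fs: float = 256.0
    n_channels: int = 4
    noise_exponent: float = 1.0
    line_freq: float = 50.0
    line_amp: float = 0.0
    blink_rate: float = 0.0          # events per minute
    blink_amp: float = 5.0
    erp_amp: float = 1.0
    erp_latency: float = 0.3
    erp_width: float = 0.1           # 2 sigma of the Gaussian deflection, s
    erd_band: tuple = (8.0, 30.0)
    erd_attenuation: float = 0.5
    hw_latency: float = 0.03
    marker_jitter_sd: float = 0.0
    tap_amp: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not self.fs > 0:
            raise InvalidArgumentError("fs must be positive")
        if self.n_channels < 1:
            raise InvalidArgumentError("n_channels must be >= 1")
        if not 0 < self.erd_attenuation <= 1:
            raise InvalidArgumentError("erd_attenuation must be in (0, 1]")
        for name in ("line_amp", "blink_rate", "blink_amp", "erp_amp",
                     "tap_amp", "marker_jitter_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be nonnegative")

    def stream_info(self, name: str = "synthetic-eeg") -> StreamInfo:
        labels = [f"ch{i}" for i in range(self.n_channels)]
        return StreamInfo(name, "eeg", labels, self.fs, source_id="eegloop-synth")


@dataclass
class SynthSession:
    """A generated recording plus the ground truth needed to score it."""

    eeg: SampleBlock
    markers: list
    truth: dict = field(default_factory=dict)
    config: SynthConfig | None = None


# ---------------------------------------------------------------------------
# background

def _one_over_f(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """Unit-variance 1/f^alpha noise via frequency-domain shaping."""
    white = rng.standard_normal(n)
    if n < 2:
        return white
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    weights = np.ones_like(freqs)
    if alpha != 0.0:
        weights[1:] = freqs[1:] ** (-alpha / 2.0)
    weights[0] = 0.0  # no DC component
    x = np.fft.irfft(spectrum * weights, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def make_background(duration: float, config: SynthConfig,
                    rng: np.random.Generator | None = None,
                    t0: float = 0.0) -> SampleBlock:
    """Generate ``floor(duration * fs)`` samples of background EEG.

    Deterministic under ``config.seed``; timestamps are ``t0 + k / fs``.
    """
    if duration < 0:
        raise InvalidArgumentError("duration must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = int(duration * config.fs)
    timestamps = t0 + np.arange(n) / config.fs
    values = np.empty((n, config.n_channels))
    for ch in range(config.n_channels):
        values[:, ch] = _one_over_f(rng, n, config.fs, config.noise_exponent)
    if config.line_amp > 0 and n:
        for ch in range(config.n_channels):
            phase = rng.uniform(0, 2 * np.pi)
            values[:, ch] += config.line_amp * np.sin(
                2 * np.pi * config.line_freq * timestamps + phase
            )
    if config.blink_rate > 0 and n:
        _add_blinks(rng, timestamps, values, config)
    return SampleBlock(timestamps, values)


def _add_blinks(rng, timestamps, values, config):
    duration = len(timestamps) / config.fs
    n_blinks = rng.poisson(config.blink_rate * duration / 60.0)
    weights = np.full(config.n_channels, 0.2)
    weights[: max(1, min(2, config.n_channels))] = 1.0
    width = 0.2  # s; <= 4 Hz energy
    for _ in range(n_blinks):
        center = rng.uniform(0, duration) + timestamps[0]
        bump = config.blink_amp * np.exp(
            -0.5 * ((timestamps - center) / (width / 2.0)) ** 2
        )
        values += np.outer(bump, weights)


def _gauss_template(timestamps, center, amp, width):
    sigma = width / 2.0
    return amp * np.exp(-0.5 * ((timestamps - center) / sigma) ** 2)


def _class_labels(n_stimuli, classes, policy, rng):
    if policy == "round-robin":
        return [classes[i % len(classes)] for i in range(n_stimuli)]
    if policy == "random":
        return [classes[i] for i in rng.integers(0, len(classes), n_stimuli)]
    raise InvalidArgumentError(f"unknown schedule policy {policy!r}")


# ---------------------------------------------------------------------------
# oddball (P300-style) sessions

def make_oddball_session(n_classes: int, n_stimuli: int, isi: float,
                         target_class: int, config: SynthConfig,
                         policy: str = "round-robin",
                         lead_in: float = 2.0) -> SynthSession:
    """Oddball run: markers for every stimulus, an evoked deflection only
    after target-class markers.

    The deflection is a Gaussian-windowed positive bump on the first half
    of the channels, centered ``hw_latency + erp_latency`` after the marker
    (plus per-stimulus Gaussian jitter of ``marker_jitter_sd``).  ``truth``
    records the target class, the per-marker labels and the true latency.
    """
    if n_classes < 2:
        raise InvalidArgumentError("need at least 2 classes")
    if not 0 <= target_class < n_classes:
        raise InvalidArgumentError(f"target_class {target_class} out of range")
    if n_stimuli < 0:
        raise InvalidArgumentError("n_stimuli must be nonnegative")
    if isi < config.erp_width:
        warnings.warn(
            f"isi {isi} s is shorter than erp_width {config.erp_width} s: "
            "evoked responses will overlap following stimuli",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    tail = config.hw_latency + config.erp_latency + 3 * config.erp_width + 1.0
    duration = lead_in + n_stimuli * isi + tail
    eeg = make_background(duration, config, rng=rng)
    labels = _class_labels(n_stimuli, list(range(n_classes)), policy, rng)
    erp_channels = np.arange(max(1, config.n_channels // 2))

    markers, effect_times = [], []
    for k, label in enumerate(labels):
        t = lead_in + k * isi
        markers.append(MarkerEvent(t, {"label": f"stim-{label}", "class": label,
                                       "phase": "stimuli"}))
        if label == target_class and config.erp_amp > 0:
            jitter = rng.normal(0.0, config.marker_jitter_sd) if config.marker_jitter_sd else 0.0
            center = t + config.hw_latency + config.erp_latency + jitter
            effect_times.append(center)
            bump = _gauss_template(eeg.timestamps, center, config.erp_amp,
                                   config.erp_width)
            eeg.values[:, erp_channels] += bump[:, None]
    truth = {
        "target_class": target_class,
        "labels": labels,
        "hw_latency": config.hw_latency,
        "erp_latency": config.erp_latency,
        "erp_channels": erp_channels.tolist(),
        "effect_times": effect_times,
    }
    return SynthSession(eeg, markers, truth, config)


# ---------------------------------------------------------------------------
# motor-imagery sessions

def _check_spd_input(cov, n_channels):
    cov = np.asarray(cov, dtype=np.float64)
    if cov.shape != (n_channels, n_channels):
        raise InvalidArgumentError(
            f"covariance shape {cov.shape} != ({n_channels}, {n_channels})"
        )
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise InvalidArgumentError("class covariance must be symmetric")
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 0:
        raise InvalidArgumentError("class covariance must be positive definite")
    return cov


def make_erd_covs(n_channels: int, attenuation: float) -> list:
    """Two class covariances differing by band-power attenuation on the
    first two channels (a minimal lateralized-desynchronization model)."""
    base = np.eye(n_channels)
    a = _spd_scale(base, 0, attenuation)
    b = _spd_scale(base, min(1, n_channels - 1), attenuation)
    return [a, b]


def _spd_scale(base, channel, attenuation):
    out = base.copy()
    out[channel, channel] *= attenuation ** 2
    return out


def make_mi_session(n_epochs_per_class: int, class_covs, config: SynthConfig,
                    epoch_duration: float = 2.0, lead_in: float = 1.0,
                    policy: str = "round-robin") -> SynthSession:
    """Motor-imagery run: contiguous labeled epochs whose band-passed
    sample covariance converges to the requested per-class SPD target.

    Per-epoch signal = white noise, band-passed to ``erd_band``, scaled to
    unit theoretical variance, then mixed through the symmetric square root
    of the class covariance — so ``class_covs[k]`` is the exact recovery
    target for class ``k``.
    """
    if n_epochs_per_class < 1:
        raise InvalidArgumentError("n_epochs_per_class must be >= 1")
    covs = [_check_spd_input(c, config.n_channels) for c in class_covs]
    if len(covs) < 1:
        raise InvalidArgumentError("need at least one class covariance")
    rng = np.random.default_rng(config.seed)

    order = min(DEFAULT_MI_TAPS, _odd_floor(int(epoch_duration * config.fs)))
    taps = design_filter(FilterSpec("bandpass", config.erd_band, order=order),
                         config.fs)
    gain = np.sqrt(np.sum(taps ** 2))
    mixers = [_sym_sqrt(c) for c in covs]

    n_classes = len(covs)
    labels = _class_labels(n_epochs_per_class * n_classes,
                           list(range(n_classes)), policy, rng)
    if policy == "random":
        # guarantee every class appears n_epochs_per_class times
        labels = [i % n_classes for i in range(n_epochs_per_class * n_classes)]
        rng.shuffle(labels)

    n_len = int(round(epoch_duration * config.fs))
    pad = len(taps)
    blocks, markers = [], []
    t = lead_in
    for label in labels:
        white = rng.standard_normal((n_len + pad, config.n_channels))
        band = signal.lfilter(taps, [1.0], white, axis=0)[pad:] / gain
        mixed = band @ mixers[label].T
        timestamps = t + np.arange(n_len) / config.fs
        blocks.append(SampleBlock(timestamps, mixed))
        markers.append(MarkerEvent(t, {"label": label, "class": label,
                                       "phase": "calibration"}))
        t += epoch_duration
    eeg = SampleBlock.concat(blocks) if blocks else SampleBlock.empty(config.n_channels)
    truth = {"labels": labels, "class_covs": [c.tolist() for c in covs],
             "epoch_duration": epoch_duration}
    return SynthSession(eeg, markers, truth, config)


DEFAULT_MI_TAPS = 129


def _odd_floor(n):
    n = max(3, n - 1)
    return n if n % 2 == 1 else n - 1


def _sym_sqrt(cov):
    w, v = np.linalg.eigh(cov)
    return (v * np.sqrt(w)) @ v.T


# ---------------------------------------------------------------------------
# tap-calibration sessions

def _tap_template(fs: float, amp: float) -> np.ndarray:
    """Sharp-onset decaying oscillation (~0.1 s) standing in for the
    mechanical artifact of a finger tap on the headset."""
    t = np.arange(int(0.1 * fs)) / fs
    return amp * np.sin(2 * np.pi * 32.0 * t) * np.exp(-t / 0.02)


def make_tap_session(n_taps: int, true_latency: float, tap_sd: float,
                     config: SynthConfig, isi: float = 1.5,
                     lead_in: float = 2.0) -> SynthSession:
    """Latency-calibration run: flash markers at known times, a large
    artifact ``true_latency + N(0, tap_sd^2)`` after each (snapped to the
    sample grid).  ``truth`` records the true latency and artifact onsets.
    """
    if n_taps < 1:
        raise InvalidArgumentError("n_taps must be >= 1")
    if tap_sd < 0:
        raise InvalidArgumentError("tap_sd must be nonnegative")
    rng = np.random.default_rng(config.seed)
    duration = lead_in + n_taps * isi + 1.0
    eeg = make_background(duration, config, rng=rng)
    template = _tap_template(config.fs, config.tap_amp)

    markers, artifact_times = [], []
    for k in range(n_taps):
        t_marker = lead_in + k * isi
        markers.append(MarkerEvent(t_marker, {"label": "flash", "phase": "calibration"}))
        offset = true_latency + (rng.normal(0.0, tap_sd) if tap_sd else 0.0)
        onset_index = int(round((t_marker + offset) * config.fs))
        onset_index = max(0, min(onset_index, eeg.n_samples - len(template)))
        artifact_times.append(onset_index / config.fs)
        if config.tap_amp > 0:
            eeg.values[onset_index:onset_index + len(template)] += template[:, None]
    truth = {"true_latency": true_latency, "tap_sd": tap_sd,
             "artifact_times": artifact_times}
    return SynthSession(eeg, markers, truth, config)


def with_seed(config: SynthConfig, seed: int) -> SynthConfig:
    """Copy of *config* with a different seed."""
    return replace(config, seed=seed)
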