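"""Stimulus-to-EEG latency calibration from tap-artifact sessions.

A human taps the headset in sync with visual flashes; the taps produce
large artifacts in the EEG.  Pairing flash markers with detected artifact
onsets measures the fixed unknown latency of the stimulus/acquisition
chain, to the accuracy of the human's tapping — tap timing noise averages
out over many taps.  Closed forms for two other latency sources (acoustic
propagation, display refresh jitter) are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, InvalidArgumentError
from .preprocess import FilterSpec, design_filter, group_delay
from .streams import SampleBlock
from scipy import signal

SPEED_OF_SOUND = 343.0  # m/s, dry air at 20 degrees C

#: Default pairing window: taps land well under half a second after a flash.
DEFAULT_MAX_OFFSET = 0.5


@dataclass(frozen=True)
class LatencyEstimate:
    """Result of a tap-calibration run (all times in milliseconds)."""

    mean_latency: float
    std_error: float
    n_pairs: int
    outliers_rejected: int = 0
    dropped_markers: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise InvalidArgumentError("n_pairs must be >= 1")
        if self.std_error < 0:
            raise InvalidArgumentError("std_error must be nonnegative")


def _robust_sd(x: np.ndarray) -> float:
    """Scaled median absolute deviation (consistent for a Gaussian)."""
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def detect_tap_artifacts(block: SampleBlock, threshold_sd: float = 5.0,
                         refractory: float = 0.25,
                         highpass_hz: float = 1.0,
                         order: int = 65) -> list:
    """Detect artifact onset times (s) in an EEG block.

    The block is high-passed at *highpass_hz* (causal linear-phase FIR,
    with the known group delay subtracted from the detected times — this
    is an offline analysis, so the compensation is legitimate), averaged
    across channels as absolute amplitude, and thresholded at
    ``threshold_sd`` robust standard deviations.  The first sample of each
    supra-threshold excursion is an onset; onsets within *refractory*
    seconds of the previous one are suppressed.  Sorted and deduplicated;
    an empty list is a valid result.
    """
    if block.n_samples == 0:
        raise InvalidArgumentError("block is empty")
    fs = block.sampling_rate()
    spec = FilterSpec("highpass", (highpass_hz,), order=order)
    taps = design_filter(spec, fs)
    filtered = signal.lfilter(taps, [1.0], block.values, axis=0)
    envelope = np.mean(np.abs(filtered), axis=1)
    scale = _robust_sd(envelope)
    if scale == 0:
        scale = float(envelope.std())
    if scale == 0:
        return []
    # envelope (mean |x|) has a nonzero baseline; threshold above its median
    threshold = float(np.median(envelope)) + threshold_sd * scale
    if not np.isfinite(threshold):
        return []
    above = envelope > threshold
    delay = group_delay(spec, fs)
    onsets = []
    last = -np.inf
    for idx in np.flatnonzero(above & ~np.roll(above, 1)):
        t = float(block.timestamps[idx]) - delay
        if t - last >= refractory:
            onsets.append(t)
            last = t
    return onsets


def estimate_latency(marker_times, artifact_times,
                     max_offset: float = DEFAULT_MAX_OFFSET,
                     outlier_sd: float = 3.0) -> LatencyEstimate:
    """Estimate the fixed marker-to-artifact latency.

    Each marker pairs with the first artifact in ``(marker, marker +
    max_offset]``; markers with no artifact in the window are dropped and
    counted.  Pair offsets farther than ``outlier_sd`` robust standard
    deviations from the median are rejected and counted.  The estimate is
    the mean offset with its standard error, in milliseconds.
    """
    marker_times = np.sort(np.asarray(marker_times, dtype=float))
    artifact_times = np.sort(np.asarray(artifact_times, dtype=float))
    if marker_times.size < 1:
        raise InvalidArgumentError("need at least one marker")
    offsets = []
    dropped = 0
    for m in marker_times:
        idx = np.searchsorted(artifact_times, m, side="right")
        if idx < artifact_times.size and artifact_times[idx] - m <= max_offset:
            offsets.append(artifact_times[idx] - m)
        else:
            dropped += 1
    if not offsets:
        raise EstimationError("no marker/artifact pairs inside the window")
    offsets = np.asarray(offsets)
    scale = _robust_sd(offsets)
    if scale > 0:
        keep = np.abs(offsets - np.median(offsets)) <= outlier_sd * scale
    else:
        keep = np.ones(offsets.size, dtype=bool)
    rejected = int(offsets.size - keep.sum())
    kept = offsets[keep]
    if kept.size == 0:
        raise EstimationError("all pairs rejected as outliers")
    sd = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    return LatencyEstimate(
        mean_latency=float(kept.mean() * 1000.0),
        std_error=sd / np.sqrt(kept.size) * 1000.0,
        n_pairs=int(kept.size),
        outliers_rejected=rejected,
        dropped_markers=dropped,
    )


def calibrate_from_session(block: SampleBlock, markers,
                           threshold_sd: float = 5.0,
                           max_offset: float = DEFAULT_MAX_OFFSET) -> LatencyEstimate:
    """Full pipeline: detect artifacts in *block*, pair against *markers*."""
    artifacts = detect_tap_artifacts(block, threshold_sd=threshold_sd)
    times = [m.timestamp for m in markers]
    return estimate_latency(times, artifacts, max_offset=max_offset)


def acoustic_latency(distance: float) -> float:
    """Sound-propagation latency over *distance* meters, in ms
    (1000 * distance / 343 — about 3 ms per meter)."""
    if distance < 0:
        raise InvalidArgumentError("distance must be nonnegative")
    return 1000.0 * distance / SPEED_OF_SOUND

def refresh_jitter_bound(refresh_rate: float) -> float:
    """Worst-case stimulus-onset jitter (ms) of an unsynchronized draw on a
    display refreshing at *refresh_rate* Hz: one full refresh period."""
    if not refresh_rate > 0:
        raise InvalidArgumentError("refresh_rate must be positive")
    return 1000.0 / refresh_rate
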