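"""Causal FIR filtering, epoching, baselining and the line-noise power check.

Filters are linear-phase window-design FIRs applied causally, so each one
carries a known group delay of ``(order - 1) / (2 * fs)`` seconds.  The
delay is reported, never silently compensated: compensation would make the
filter non-causal.  Callers that epoch filtered data may shift their epoch
windows by the reported delay instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import FilterStateError, InvalidArgumentError
from .streams import MarkerEvent, SampleBlock

FILTER_KINDS = ("bandpass", "highpass", "lowpass", "notch")

#: Default motor-imagery band (Hz) and FIR length at 256 Hz.
DEFAULT_MI_BAND = (8.0, 30.0)
DEFAULT_FIR_ORDER = 129


# ---------------------------------------------------------------------------
# filter design & causal application

@dataclass(frozen=True)
class FilterSpec:
    """Specification of one FIR filter.

    ``band`` is a ``(low, high)`` pair for bandpass/notch and a single edge
    (scalar or 1-tuple) for highpass/lowpass.  ``order`` is the number of
    taps and must be odd so the filter is Type-I linear phase for every
    kind.
    """

    kind: str
    band: tuple
    order: int = DEFAULT_FIR_ORDER
    design: str = "fir-window"
    causal: bool = True

    def __post_init__(self):
        if self.kind not in FILTER_KINDS:
            raise InvalidArgumentError(f"kind must be one of {FILTER_KINDS}")
        if self.design != "fir-window":
            raise InvalidArgumentError("only the fir-window design is implemented")
        if self.order < 3 or self.order % 2 == 0:
            raise InvalidArgumentError("order must be an odd integer >= 3")
        band = self.band if isinstance(self.band, (tuple, list)) else (self.band,)
        band = tuple(float(b) for b in band)
        expected = 2 if self.kind in ("bandpass", "notch") else 1
        if len(band) != expected:
            raise InvalidArgumentError(
                f"{self.kind} needs {expected} band edge(s), got {len(band)}"
            )
        if len(band) == 2 and not band[0] < band[1]:
            raise InvalidArgumentError("band edges must be increasing")
        object.__setattr__(self, "band", band)

    def edges(self):
        return self.band


def design_filter(spec: FilterSpec, fs: float) -> np.ndarray:
    """Design the FIR taps for *spec* at sampling rate *fs* (Hamming window)."""
    if not fs > 0:
        raise InvalidArgumentError("fs must be positive")
    nyq = fs / 2.0
    edges = spec.edges()
    if any(not 0 < e < nyq for e in edges):
        raise InvalidArgumentError(
            f"band edges {edges} must lie strictly inside (0, {nyq}) Hz"
        )
    pass_zero = {"bandpass": False, "highpass": False,
                 "lowpass": True, "notch": True}[spec.kind]
    return signal.firwin(spec.order, edges, pass_zero=pass_zero,
                         window="hamming", fs=fs)


def notch_spec(f0: float, bw: float = 4.0, order: int = DEFAULT_FIR_ORDER) -> FilterSpec:
    """Convenience: a notch (band-stop) spec centered at *f0* with width *bw*."""
    return FilterSpec("notch", (f0 - bw / 2.0, f0 + bw / 2.0), order=order)


def group_delay(spec: FilterSpec, fs: float) -> float:
    """Group delay of the linear-phase FIR, in seconds."""
    return (spec.order - 1) / (2.0 * fs)


def filter_gain(coeffs: np.ndarray, freq: float, fs: float) -> float:
    """Magnitude response of *coeffs* at *freq* Hz (DTFT of the taps)."""
    _, h = signal.freqz(coeffs, worN=[freq], fs=fs)
    return float(np.abs(h[0]))


class FilterState:
    """Carry-over state for chunked causal filtering (one per stream)."""

    def __init__(self, coeffs: np.ndarray, n_channels: int):
        self.coeffs = np.asarray(coeffs, dtype=np.float64)
        self.n_channels = int(n_channels)
        self.zi = np.zeros((len(self.coeffs) - 1, self.n_channels))


def apply_causal(coeffs: np.ndarray, block: SampleBlock,
                 state: FilterState | None = None):
    """Filter *block* causally, carrying state across calls.

    Output at sample index ``t`` depends only on inputs at indices
    ``<= t``; splitting a signal into chunks and filtering each with the
    returned state gives the same result as filtering the concatenation in
    one call.

    Returns ``(filtered_block, state)``.
    """
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if state is None:
        state = FilterState(coeffs, block.n_channels)
    if state.n_channels != block.n_channels:
        raise FilterStateError(
            f"state holds {state.n_channels} channels, block has {block.n_channels}"
        )
    if len(state.coeffs) != len(coeffs) or not np.array_equal(state.coeffs, coeffs):
        raise FilterStateError("state was created for different coefficients")
    if block.n_samples == 0:
        return block, state
    out, state.zi = signal.lfilter(coeffs, [1.0], block.values, axis=0, zi=state.zi)
    return SampleBlock(block.timestamps.copy(), out), state


# ---------------------------------------------------------------------------
# epoching

@dataclass(frozen=True)
class EpochSpec:
    """Time-locked epoch window relative to a marker onset (seconds)."""

    t_min: float
    t_max: float
    baseline: tuple | None = None

    def __post_init__(self):
        if not self.t_max > self.t_min:
            raise InvalidArgumentError("t_max must exceed t_min")
        if self.baseline is not None:
            b0, b1 = self.baseline
            if not (self.t_min <= b0 < b1 <= self.t_max):
                raise InvalidArgumentError("baseline window must lie within the epoch")


@dataclass
class Epoch:
    """A channels x samples matrix tied to an onset time.

    ``meta`` records at least ``fs`` and ``t_min`` so windows expressed
    relative to the onset can be mapped back to columns.
    """

    onset: float
    data: np.ndarray
    label: object = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.shape[1] < 2:
            raise InvalidArgumentError("an epoch needs at least 2 samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def epoch_timelocked(block: SampleBlock, markers, spec: EpochSpec,
                     fs: float | None = None):
    """Cut one epoch per marker, time-locked to the marker timestamp.

    The epoch starts at the first sample whose timestamp is at or after
    ``onset + t_min`` (half-open window ``[onset+t_min, onset+t_max)``) and
    spans ``round((t_max - t_min) * fs)`` samples.  Markers whose window is
    not fully covered by the block are skipped, not errors.

    Returns ``(epochs, skips)`` where *skips* is a list of
    ``(marker, reason)`` pairs; ``len(markers) == len(epochs) + len(skips)``.
    """
    if fs is None:
        fs = block.sampling_rate()
    n_samples = int(round((spec.t_max - spec.t_min) * fs))
    if n_samples < 2:
        raise InvalidArgumentError("epoch window shorter than 2 samples")
    epochs, skips = [], []
    ts = block.timestamps
    for marker in markers:
        start_time = marker.timestamp + spec.t_min
        start = int(np.searchsorted(ts, start_time, side="left"))
        if start >= block.n_samples or start + n_samples > block.n_samples:
            skips.append((marker, "insufficient data"))
            continue
        if ts[start] - start_time >= 1.0 / fs:
            skips.append((marker, "no sample within one period of window start"))
            continue
        epochs.append(Epoch(
            onset=marker.timestamp,
            data=block.values[start:start + n_samples].T.copy(),
            label=marker.payload.get("label") if marker.payload.get("label") is not None
            else marker.payload.get("class"),
            meta={"fs": fs, "t_min": spec.t_min, "t_max": spec.t_max,
                  "start_index": start, **marker.payload},
        ))
    return epochs, skips


def epoch_rolling(block: SampleBlock, length: float, step: float,
                  fs: float | None = None):
    """Cut unlabeled epochs on a rolling window (possibly overlapping).

    For a block of duration ``T >= length`` the count is
    ``floor((T - length) / step) + 1``; shorter blocks give an empty list.
    """
    if not (length > 0 and step > 0):
        raise InvalidArgumentError("length and step must be positive")
    if block.n_samples < 2:
        return []
    if fs is None:
        fs = block.sampling_rate()
    n_len = int(round(length * fs))
    n_step = max(1, int(round(step * fs)))
    if n_len < 2 or n_len > block.n_samples:
        return []
    epochs = []
    for start in range(0, block.n_samples - n_len + 1, n_step):
        epochs.append(Epoch(
            onset=float(block.timestamps[start]),
            data=block.values[start:start + n_len].T.copy(),
            label=None,
            meta={"fs": fs, "t_min": 0.0, "t_max": length, "start_index": start},
        ))
    return epochs


def baseline_correct(epoch: Epoch, window: tuple) -> Epoch:
    """Subtract each channel's mean over the baseline *window* (onset-relative s).

    Exact by construction: the corrected epoch's per-channel mean over the
    window is zero to float rounding, and the operation is idempotent.  No
    processing delay is added — the correction only uses samples already in
    the epoch.
    """
    fs = epoch.meta.get("fs")
    t_min = epoch.meta.get("t_min", 0.0)
    if fs is None:
        raise InvalidArgumentError("epoch.meta must record 'fs'")
    b0, b1 = window
    i0 = int(round((b0 - t_min) * fs))
    i1 = int(round((b1 - t_min) * fs))
    i0 = max(i0, 0)
    i1 = min(i1, epoch.n_samples)
    if i1 <= i0:
        raise InvalidArgumentError("baseline window is empty within this epoch")
    means = epoch.data[:, i0:i1].mean(axis=1, keepdims=True)
    return Epoch(epoch.onset, epoch.data - means, epoch.label, dict(epoch.meta))


# ---------------------------------------------------------------------------
# line-noise power (electrode-impedance proxy)

def narrowband_power(block: SampleBlock, f0: float, bw: float = 4.0,
                     fs: float | None = None, order: int = DEFAULT_FIR_ORDER) -> np.ndarray:
    """Mean squared amplitude per channel in a narrow band around *f0* Hz.

    High line-frequency power flags poor electrode contact.  The band must
    stay above 1 Hz, the recommended high-pass floor for this check.  The
    filter's startup transient is excluded from the power estimate.
    """
    if fs is None:
        fs = block.sampling_rate()
    lo, hi = f0 - bw / 2.0, f0 + bw / 2.0
    if not (1.0 < lo and hi < fs / 2.0):
        raise InvalidArgumentError(
            f"band [{lo}, {hi}] must lie inside (1, {fs / 2}) Hz"
        )
    if block.n_samples == 0:
        return np.zeros(block.n_channels)
    spec = FilterSpec("bandpass", (lo, hi), order=min(order, _odd_cap(block.n_samples)))
    taps = design_filter(spec, fs)
    filtered = signal.lfilter(taps, [1.0], block.values, axis=0)
    skip = min(len(taps), block.n_samples - 1)
    steady = filtered[skip:] if block.n_samples > len(taps) else filtered
    return np.mean(steady ** 2, axis=0)


def _odd_cap(n: int) -> int:
    n = max(3, n)
    return n if n % 2 == 1 else n - 1


def marker_in_span(marker: MarkerEvent, block: SampleBlock) -> bool:
    """True if the marker timestamp lies within the block's time span."""
    if block.n_samples == 0:
        return False
    return bool(block.timestamps[0] <= marker.timestamp <= block.timestamps[-1])
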