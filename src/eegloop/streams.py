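"""Typed stream primitives: stream metadata, timestamped sample blocks, markers.

All timestamps in the package are seconds on a single monotonic session
clock, stored as 64-bit floats.  Hardware sources with their own time base
are normalized at ingest via :attr:`StreamInfo.clock_offset`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

STREAM_TYPES = ("eeg", "markers", "messages")


@dataclass
class StreamInfo:
    """Metadata describing one stream.

    Parameters
    ----------
    name : str
        Human-readable stream identifier.
    stream_type : {"eeg", "markers", "messages"}
        Regular signal streams carry a positive nominal rate; marker and
        message streams are irregular (``nominal_rate == 0``).
    channel_labels : list of str
        One label per channel.  Marker streams have a single channel.
    nominal_rate : float
        Sampling rate in Hz; 0 for irregular streams.
    source_id : str
        Stable identifier of the producing device or generator.
    clock_offset : float
        Declared offset (s) added to raw device timestamps at ingest to map
        them onto the session clock.
    """

    name: str
    stream_type: str
    channel_labels: list
    nominal_rate: float
    source_id: str = ""
    clock_offset: float = 0.0

    def __post_init__(self):
        if self.stream_type not in STREAM_TYPES:
            raise InvalidArgumentError(
                f"stream_type must be one of {STREAM_TYPES}, got {self.stream_type!r}"
            )
        self.channel_labels = list(self.channel_labels)
        if self.stream_type == "eeg":
            if not self.nominal_rate > 0:
                raise InvalidArgumentError("eeg streams require nominal_rate > 0")
            if len(self.channel_labels) < 1:
                raise InvalidArgumentError("eeg streams require at least one channel")
        elif self.nominal_rate != 0:
            raise InvalidArgumentError(
                f"{self.stream_type} streams are irregular; nominal_rate must be 0"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)


@dataclass
class SampleBlock:
    """A chunk of regularly sampled multichannel signal.

    ``values`` is oriented samples x channels: streaming appends rows.
    Epochs (channels x samples) are produced exactly once, at epoching.
    """

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.timestamps.ndim != 1:
            raise InvalidArgumentError("timestamps must be one-dimensional")
        if self.timestamps.size == 0 and self.values.ndim == 2:
            self.values = self.values.reshape(0, self.values.shape[1])
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise InvalidArgumentError(
                f"values has {self.values.shape[0]} rows but there are "
                f"{self.timestamps.shape[0]} timestamps"
            )
        if self.timestamps.size > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def sampling_rate(self) -> float:
        """Sampling rate inferred from the median timestamp spacing."""
        if self.n_samples < 2:
            raise InvalidArgumentError("need at least two samples to infer a rate")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    @classmethod
    def empty(cls, n_channels: int) -> "SampleBlock":
        return cls(np.empty(0), np.empty((0, n_channels)))

    @classmethod
    def concat(cls, blocks) -> "SampleBlock":
        blocks = [b for b in blocks if b.n_samples > 0]
        if not blocks:
            raise InvalidArgumentError("cannot concatenate zero non-empty blocks")
        return cls(
            np.concatenate([b.timestamps for b in blocks]),
            np.concatenate([b.values for b in blocks], axis=0),
        )


@dataclass(frozen=True)
class MarkerEvent:
    """An irregularly timed event with a textual payload.

    The payload is a flat mapping and must at least support the keys
    ``label``, ``class`` and ``phase`` (all optional per event).
    """

    timestamp: float
    payload: dict = field(default_factory=dict)

    def __post_init__(self):
        if not math.isfinite(self.timestamp):
            raise InvalidArgumentError("marker timestamp must be finite")
        object.__setattr__(self, "payload", dict(self.payload))

    @property
    def label(self):
        return self.payload.get("label")

    @property
    def klass(self):
        return self.payload.get("class")

    @property
    def phase(self):
        return self.payload.get("phase")
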