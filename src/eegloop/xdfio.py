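"""Recording I/O: XDF container files and a plain-text CSV fallback.

The XDF writer/reader implements the standard chunked container layout
(magic ``XDF:``, variable-length chunk sizes, FileHeader / StreamHeader /
Samples / StreamFooter chunks) so recordings interoperate with external
XDF tooling.  Signal streams are stored as ``double64`` channels with one
64-bit timestamp per sample; marker streams as a single ``string`` channel
holding the JSON-serialized payload.

CSV fallback: one file per stream — a timestamp column plus one column per
channel for signals; ``timestamp,label,class,phase,extra`` for markers.
Floats are written with ``repr`` so the round trip is exact for float64.
"""

from __future__ import annotations

import csv
import io
import json
import struct
import xml.etree.ElementTree as ET

import numpy as np

from .errors import FormatError, InvalidArgumentError
from .streams import MarkerEvent, SampleBlock, StreamInfo

_MAGIC = b"XDF:"
_TAG_FILE_HEADER = 1
_TAG_STREAM_HEADER = 2
_TAG_SAMPLES = 3
_TAG_CLOCK_OFFSET = 4
_TAG_BOUNDARY = 5
_TAG_STREAM_FOOTER = 6


# ---------------------------------------------------------------------------
# low-level chunk helpers

def _write_varlen(buf, value: int) -> None:
    if value < 256:
        buf.write(b"\x01" + struct.pack("<B", value))
    elif value < 2 ** 32:
        buf.write(b"\x04" + struct.pack("<I", value))
    else:
        buf.write(b"\x08" + struct.pack("<Q", value))


def _write_chunk(fh, tag: int, content: bytes) -> None:
    buf = io.BytesIO()
    _write_varlen(buf, len(content) + 2)
    fh.write(buf.getvalue())
    fh.write(struct.pack("<H", tag))
    fh.write(content)


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def read(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise FormatError("truncated file", offset=self.pos)
        out = self.data[self.pos:self.pos + n]
        self.pos += n
        return out

    def read_varlen(self) -> int:
        nbytes = self.read(1)[0]
        if nbytes == 1:
            return self.read(1)[0]
        if nbytes == 4:
            return struct.unpack("<I", self.read(4))[0]
        if nbytes == 8:
            return struct.unpack("<Q", self.read(8))[0]
        raise FormatError(f"bad length-field size {nbytes}", offset=self.pos - 1)

    @property
    def exhausted(self) -> bool:
        return self.pos >= len(self.data)


# ---------------------------------------------------------------------------
# stream <-> XML

def _info_to_xml(info: StreamInfo, channel_format: str) -> bytes:
    root = ET.Element("info")
    ET.SubElement(root, "name").text = info.name
    ET.SubElement(root, "type").text = info.stream_type
    ET.SubElement(root, "channel_count").text = str(info.n_channels)
    ET.SubElement(root, "nominal_srate").text = repr(float(info.nominal_rate))
    ET.SubElement(root, "channel_format").text = channel_format
    ET.SubElement(root, "source_id").text = info.source_id
    desc = ET.SubElement(root, "desc")
    ET.SubElement(desc, "clock_offset").text = repr(float(info.clock_offset))
    channels = ET.SubElement(desc, "channels")
    for label in info.channel_labels:
        ch = ET.SubElement(channels, "channel")
        ET.SubElement(ch, "label").text = label
    return ET.tostring(root, encoding="unicode").encode("utf-8")


def _info_from_xml(blob: bytes) -> tuple:
    try:
        root = ET.fromstring(blob.decode("utf-8"))
    except ET.ParseError as exc:
        raise FormatError(f"bad stream header XML: {exc}") from exc

    def text(tag, default=""):
        el = root.find(tag)
        return el.text if el is not None and el.text is not None else default

    labels = [
        (ch.findtext("label") or "")
        for ch in root.findall("desc/channels/channel")
    ]
    info = StreamInfo(
        name=text("name"),
        stream_type=text("type", "eeg"),
        channel_labels=labels or [""] * int(text("channel_count", "1")),
        nominal_rate=float(text("nominal_srate", "0")),
        source_id=text("source_id"),
        clock_offset=float(text("desc/clock_offset", "0.0")),
    )
    return info, text("channel_format", "double64")


# ---------------------------------------------------------------------------
# XDF write / read

def write_xdf(path, streams) -> None:
    """Write ``[(StreamInfo, SampleBlock | list[MarkerEvent]), ...]`` to *path*."""
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        _write_chunk(
            fh, _TAG_FILE_HEADER,
            b'<?xml version="1.0"?><info><version>1.0</version></info>',
        )
        for sid, (info, data) in enumerate(streams, start=1):
            is_markers = isinstance(data, (list, tuple))
            fmt = "string" if is_markers else "double64"
            if not is_markers and data.n_channels != info.n_channels:
                raise InvalidArgumentError(
                    f"stream {info.name!r}: block has {data.n_channels} channels, "
                    f"info declares {info.n_channels}"
                )
            _write_chunk(fh, _TAG_STREAM_HEADER,
                         struct.pack("<I", sid) + _info_to_xml(info, fmt))

            buf = io.BytesIO()
            buf.write(struct.pack("<I", sid))
            if is_markers:
                _write_varlen(buf, len(data))
                for ev in data:
                    buf.write(b"\x08" + struct.pack("<d", ev.timestamp))
                    blob = json.dumps(ev.payload, sort_keys=True).encode("utf-8")
                    _write_varlen(buf, len(blob))
                    buf.write(blob)
                n_samples = len(data)
                t0 = data[0].timestamp if data else 0.0
                t1 = data[-1].timestamp if data else 0.0
            else:
                _write_varlen(buf, data.n_samples)
                for ts, row in zip(data.timestamps, data.values):
                    buf.write(b"\x08" + struct.pack("<d", ts))
                    buf.write(np.asarray(row, dtype="<f8").tobytes())
                n_samples = data.n_samples
                t0 = data.timestamps[0] if n_samples else 0.0
                t1 = data.timestamps[-1] if n_samples else 0.0
            _write_chunk(fh, _TAG_SAMPLES, buf.getvalue())

            footer = (
                "<info><first_timestamp>{}</first_timestamp>"
                "<last_timestamp>{}</last_timestamp>"
                "<sample_count>{}</sample_count></info>"
            ).format(repr(float(t0)), repr(float(t1)), n_samples)
            _write_chunk(fh, _TAG_STREAM_FOOTER,
                         struct.pack("<I", sid) + footer.encode("utf-8"))


def read_xdf(path):
    """Read an XDF file; returns the same structure :func:`write_xdf` takes."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != _MAGIC:
        raise FormatError("not an XDF file (bad magic)", offset=0)
    rd = _Reader(data)
    rd.pos = 4

    headers: dict[int, tuple] = {}
    samples: dict[int, list] = {}
    order: list[int] = []
    while not rd.exhausted:
        chunk_start = rd.pos
        length = rd.read_varlen()
        if length < 2:
            raise FormatError("chunk shorter than its tag", offset=chunk_start)
        tag = struct.unpack("<H", rd.read(2))[0]
        content = _Reader(rd.read(length - 2))
        if tag == _TAG_STREAM_HEADER:
            sid = struct.unpack("<I", content.read(4))[0]
            headers[sid] = _info_from_xml(content.data[content.pos:])
            samples.setdefault(sid, [])
            order.append(sid)
        elif tag == _TAG_SAMPLES:
            sid = struct.unpack("<I", content.read(4))[0]
            if sid not in headers:
                raise FormatError(f"samples for undeclared stream {sid}",
                                  offset=chunk_start)
            info, fmt = headers[sid]
            n = content.read_varlen()
            for _ in range(n):
                ts_bytes = content.read(1)[0]
                ts = struct.unpack("<d", content.read(8))[0] if ts_bytes == 8 else None
                if fmt == "string":
                    blob = content.read(content.read_varlen())
                    samples[sid].append((ts, blob))
                else:
                    raw = content.read(8 * info.n_channels)
                    samples[sid].append((ts, np.frombuffer(raw, dtype="<f8")))
        elif tag in (_TAG_FILE_HEADER, _TAG_CLOCK_OFFSET, _TAG_BOUNDARY,
                     _TAG_STREAM_FOOTER):
            pass
        else:
            raise FormatError(f"unknown chunk tag {tag}", offset=chunk_start)

    out = []
    for sid in order:
        info, fmt = headers[sid]
        rows = samples[sid]
        if fmt == "string":
            events = [
                MarkerEvent(ts, json.loads(blob.decode("utf-8")))
                for ts, blob in rows
            ]
            out.append((info, events))
        else:
            if rows:
                ts = np.array([r[0] for r in rows], dtype=np.float64)
                vals = np.vstack([r[1] for r in rows])
            else:
                ts = np.empty(0)
                vals = np.empty((0, info.n_channels))
            out.append((info, SampleBlock(ts, vals)))
    return out


# ---------------------------------------------------------------------------
# CSV fallback

_MARKER_FIELDS = ("label", "class", "phase")


def write_csv_stream(path, info: StreamInfo, data) -> None:
    """Write one stream as CSV (see module docstring for the layout)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if isinstance(data, (list, tuple)):
            writer.writerow(("timestamp",) + _MARKER_FIELDS + ("extra",))
            for ev in data:
                extra = {k: v for k, v in ev.payload.items() if k not in _MARKER_FIELDS}
                writer.writerow(
                    [repr(float(ev.timestamp))]
                    + [_cell(ev.payload.get(k)) for k in _MARKER_FIELDS]
                    + [json.dumps(extra, sort_keys=True) if extra else ""]
                )
        else:
            writer.writerow(["timestamp"] + list(info.channel_labels))
            for ts, row in zip(data.timestamps, data.values):
                writer.writerow([repr(float(ts))] + [repr(float(v)) for v in row])


def _cell(value) -> str:
    if value is None:
        return ""
    return json.dumps(value) if not isinstance(value, str) else value


def _uncell(text: str):
    if text == "":
        return None
    try:
        return json.loads(text)
    except (json.JSONDecodeError, ValueError):
        return text


def read_csv_stream(path, info: StreamInfo):
    """Read a stream written by :func:`write_csv_stream`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty CSV") from None
        rows = list(reader)
    if header[:1] != ["timestamp"]:
        raise FormatError(f"{path}: first column must be 'timestamp'")
    if tuple(header[1:4]) == _MARKER_FIELDS:
        events = []
        for row in rows:
            payload = {k: _uncell(v) for k, v in zip(_MARKER_FIELDS, row[1:4])
                       if _uncell(v) is not None}
            if len(row) > 4 and row[4]:
                payload.update(json.loads(row[4]))
            events.append(MarkerEvent(float(row[0]), payload))
        return events
    ts = np.array([float(r[0]) for r in rows], dtype=np.float64)
    vals = (np.array([[float(v) for v in r[1:]] for r in rows], dtype=np.float64)
            if rows else np.empty((0, info.n_channels)))
    return SampleBlock(ts, vals)
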