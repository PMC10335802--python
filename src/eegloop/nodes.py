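"""Graph-node wrappers around the processing primitives.

Registering these kinds makes them available to graph configuration files
("bandpass", "epoch", "oddoneout", ...).  Nodes are thin: they keep the
streaming state (filter taps and carry-over, epoch buffers, running
odd-one-out ensembles) and delegate the math to the underlying modules.
"""

from __future__ import annotations

import numpy as np

from . import preprocess, riemann
from .graph import Node, register_node
from .oddball import OddOneOutState
from .streams import MarkerEvent, SampleBlock


@register_node("counter")
class CounterNode(Node):
    """Increments ``count`` once per tick; handy for scheduling tests."""

    def setup(self):
        self.count = 0

    def update(self):
        self.count += 1
        self.outputs["out"] = self.count


@register_node("block_source")
class BlockSourceNode(Node):
    """Replays a preloaded :class:`SampleBlock`, emitting on each tick the
    samples whose timestamps have passed the simulated clock."""

    def setup(self):
        self.block: SampleBlock = self.params["block"]
        self._cursor = 0

    def update(self):
        end = int(np.searchsorted(self.block.timestamps, self.clock, side="right"))
        if end > self._cursor:
            self.outputs["out"] = SampleBlock(
                self.block.timestamps[self._cursor:end],
                self.block.values[self._cursor:end],
            )
            self._cursor = end


@register_node("marker_source")
class MarkerSourceNode(Node):
    """Replays a preloaded marker list against the simulated clock."""

    def setup(self):
        self.markers = sorted(self.params["markers"], key=lambda m: m.timestamp)
        self._cursor = 0

    def update(self):
        due = []
        while (self._cursor < len(self.markers)
               and self.markers[self._cursor].timestamp <= self.clock):
            due.append(self.markers[self._cursor])
            self._cursor += 1
        if due:
            self.outputs["out"] = due


class _FilterNode(Node):
    """Shared streaming-FIR machinery for bandpass/notch nodes."""

    def _spec(self) -> preprocess.FilterSpec:  # pragma: no cover - abstract
        raise NotImplementedError

    def setup(self):
        self._taps = None
        self._state = None

    def update(self):
        chunk = self.inputs.get("in")
        if chunk is None or chunk.n_samples == 0:
            return
        if self._taps is None:
            fs = self.params.get("fs") or chunk.sampling_rate()
            self._taps = preprocess.design_filter(self._spec(), fs)
        out, self._state = preprocess.apply_causal(self._taps, chunk, self._state)
        self.outputs["out"] = out


@register_node("bandpass")
class BandpassNode(_FilterNode):
    def _spec(self):
        return preprocess.FilterSpec(
            "bandpass",
            tuple(self.params.get("band", preprocess.DEFAULT_MI_BAND)),
            order=self.params.get("order", preprocess.DEFAULT_FIR_ORDER),
        )


@register_node("notch")
class NotchNode(_FilterNode):
    def _spec(self):
        return preprocess.notch_spec(
            self.params.get("f0", 50.0),
            self.params.get("bw", 4.0),
            self.params.get("order", preprocess.DEFAULT_FIR_ORDER),
        )


@register_node("epoch")
class EpochNode(Node):
    """Buffers the signal and cuts time-locked epochs as soon as each
    pending marker's window is fully covered by the buffered data."""

    def setup(self):
        self.spec = preprocess.EpochSpec(
            t_min=self.params.get("t_min", 0.0),
            t_max=self.params.get("t_max", 0.8),
        )
        self._blocks: list = []
        self._pending: list = []
        self.skips: list = []

    def update(self):
        chunk = self.inputs.get("in")
        if chunk is not None and chunk.n_samples:
            self._blocks.append(chunk)
        markers = self.inputs.get("markers")
        if markers:
            self._pending.extend(markers)
        if not self._blocks or not self._pending:
            return
        block = SampleBlock.concat(self._blocks)
        fs = self.params.get("fs") or block.sampling_rate()
        ready = [m for m in self._pending
                 if m.timestamp + self.spec.t_max + 1.0 / fs <= block.timestamps[-1]]
        if not ready:
            return
        epochs, skips = preprocess.epoch_timelocked(block, ready, self.spec, fs=fs)
        self.skips.extend(skips)
        ready_ids = {id(m) for m in ready}
        self._pending = [m for m in self._pending if id(m) not in ready_ids]
        if epochs:
            self.outputs["out"] = epochs


@register_node("window")
class WindowNode(Node):
    """Rolling (possibly overlapping) unlabeled epochs from the live stream."""

    def setup(self):
        self.length = self.params.get("length", 1.0)
        self.step = self.params.get("step", self.length)
        self._blocks: list = []
        self._emitted = 0

    def update(self):
        chunk = self.inputs.get("in")
        if chunk is not None and chunk.n_samples:
            self._blocks.append(chunk)
        if not self._blocks:
            return
        block = SampleBlock.concat(self._blocks)
        epochs = preprocess.epoch_rolling(block, self.length, self.step)
        if len(epochs) > self._emitted:
            self.outputs["out"] = epochs[self._emitted:]
            self._emitted = len(epochs)


@register_node("baseline")
class BaselineNode(Node):
    def update(self):
        epochs = self.inputs.get("in")
        if not epochs:
            return
        window = tuple(self.params["window"])
        self.outputs["out"] = [preprocess.baseline_correct(ep, window)
                               for ep in epochs]


@register_node("linepower")
class LinePowerNode(Node):
    """Per-channel narrowband power around the line frequency, published on
    the "quality" topic as a cheap electrode-contact indicator."""

    def update(self):
        chunk = self.inputs.get("in")
        if chunk is None or chunk.n_samples < 8:
            return
        power = preprocess.narrowband_power(
            chunk, self.params.get("f0", 50.0), self.params.get("bw", 4.0)
        )
        self.outputs["out"] = power
        if self.broker is not None:
            self.broker.publish("quality", power, timestamp=self.clock)


@register_node("oddoneout")
class OddOneOutNode(Node):
    """Accumulates class-labeled epochs and republishes the running
    odd-one-out result on the "classification" topic after each update."""

    def setup(self):
        self.state = OddOneOutState(
            class_ids=list(self.params["class_ids"]),
            mode=self.params.get("mode", "avg-then-cov"),
            spec=riemann.CovSpec(shrinkage=self.params.get("shrinkage", 0.05)),
            metric=self.params.get("metric", "airm"),
        )
        self.results: list = []

    def update(self):
        epochs = self.inputs.get("in")
        if not epochs:
            return
        for ep in epochs:
            result = self.state.update(ep, ep.meta.get("class", ep.label))
            self.results.append(result)
            if self.broker is not None:
                self.broker.publish("classification", result, timestamp=self.clock)
        self.outputs["out"] = self.results[-1]


@register_node("training")
class TrainingNode(Node):
    """Collects labeled epochs; on a "train" command from the "commands"
    topic fits an MDM model, saves it to disk, and announces readiness."""

    def setup(self):
        self.epochs: list = []
        self.bundle = None

    def update(self):
        epochs = self.inputs.get("in")
        if epochs:
            self.epochs.extend(epochs)
        if self.broker is None:
            return
        for _, message in self.broker.drain("commands"):
            if isinstance(message, dict) and message.get("cmd") == "train":
                model = riemann.mdm_fit(
                    self.epochs,
                    spec=riemann.CovSpec(shrinkage=self.params.get("shrinkage", 0.05)),
                    metric=self.params.get("metric", "airm"),
                )
                self.bundle = riemann.ModelBundle(model)
                path = self.params.get("model_path")
                if path:
                    riemann.save_model(self.bundle, path)
                self.broker.publish("messages",
                                    {"cmd": "model-ready", "path": path},
                                    timestamp=self.clock)


@register_node("inference")
class InferenceNode(Node):
    """Loads the trained model once announced, then classifies every
    incoming epoch, publishing scores on the "classification" topic."""

    def setup(self):
        self.bundle = None

    def update(self):
        if self.broker is not None and self.bundle is None:
            for _, message in self.broker.drain("messages"):
                if isinstance(message, dict) and message.get("cmd") == "model-ready":
                    path = message.get("path")
                    if path:
                        self.bundle = riemann.load_model(path)
        epochs = self.inputs.get("in")
        if not epochs or self.bundle is None:
            return
        predictions = [riemann.mdm_predict(self.bundle.model, ep) for ep in epochs]
        self.outputs["out"] = predictions
        if self.broker is not None:
            for pred in predictions:
                self.broker.publish("classification", pred, timestamp=self.clock)


@register_node("pub")
class PubNode(Node):
    def update(self):
        value = self.inputs.get("in")
        if value is not None and self.broker is not None:
            self.broker.publish(self.params["topic"], value, timestamp=self.clock)


@register_node("sub")
class SubNode(Node):
    def update(self):
        if self.broker is not None:
            items = self.broker.drain(self.params["topic"])
            if items:
                self.outputs["out"] = [data for _, data in items]
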