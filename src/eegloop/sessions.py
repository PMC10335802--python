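"""Session state machines, stimulus sequencing, archiving, and the two
reference applications (motor imagery and the unsupervised oddball game).

The controllers are deterministic finite-state machines: ``(state, input)``
has a unique successor, every transition emits a phase marker, and invalid
commands are rejected with the current phase named, leaving the state
unchanged.  Applications archive their raw (pre-filter) streams plus a
manifest of seeds and config digests sufficient to re-run the whole
pipeline offline and reproduce every online decision bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
import shutil
import tempfile
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import nodes  # noqa: F401  (populates the node registry)
from .broker import Broker
from .errors import EEGLoopError, InvalidArgumentError, InvalidCommandError
from .graph import Graph, GraphSpec, run_graphs
from .preprocess import EpochSpec, epoch_timelocked
from .streams import MarkerEvent, SampleBlock, StreamInfo
from .synth import SynthConfig, make_mi_session, make_oddball_session
from .xdfio import read_csv_stream, write_csv_stream

SCHEDULE_POLICIES = ("random", "round-robin")


# ---------------------------------------------------------------------------
# stimulus sequencing

@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered (time, class id) presentation plan."""

    entries: tuple
    policy: str
    rate: float
    seed: int

    def class_counts(self) -> dict:
        counts: dict = {}
        for _, c in self.entries:
            counts[c] = counts.get(c, 0) + 1
        return counts


def make_stimulus_sequence(n: int, classes, policy: str = "round-robin",
                           rate: float = 3.0, seed: int = 0,
                           start: float = 0.0) -> StimulusSchedule:
    """Plan *n* stimuli at ``1/rate`` spacing.

    Round-robin cycles the classes in their given order (class counts
    differ by at most one); random draws i.i.d. uniformly under *seed*.
    """
    if n < 0:
        raise InvalidArgumentError("n must be nonnegative")
    if not rate > 0:
        raise InvalidArgumentError("rate must be positive")
    classes = list(classes)
    if not classes:
        raise InvalidArgumentError("class list must be non-empty")
    if policy not in SCHEDULE_POLICIES:
        raise InvalidArgumentError(f"policy must be one of {SCHEDULE_POLICIES}")
    if policy == "round-robin":
        labels = [classes[i % len(classes)] for i in range(n)]
    else:
        rng = np.random.default_rng(seed)
        labels = [classes[i] for i in rng.integers(0, len(classes), n)]
    entries = tuple((start + k / rate, labels[k]) for k in range(n))
    return StimulusSchedule(entries, policy, rate, seed)


# ---------------------------------------------------------------------------
# session state machines

@dataclass
class SessionState:
    app: str
    phase: str
    clock: float = 0.0
    paused: bool = False
    metadata: dict = field(default_factory=dict)


MI_COMMANDS = {
    # (phase, command) -> next phase
    ("idle", "start"): "calibration",
    ("calibration", "train"): "training",
    ("training", "model-ready"): "feedback",
    ("feedback", "stop"): "done",
    ("calibration", "cancel"): "done",
    ("training", "cancel"): "done",
    ("feedback", "cancel"): "done",
}

MI_PHASES = ("idle", "calibration", "training", "feedback", "done")


def _phase_marker(clock: float, phase: str, app: str) -> MarkerEvent:
    return MarkerEvent(clock, {"label": f"phase:{phase}", "phase": phase, "app": app})


class MIController:
    """Calibration -> training -> feedback session driver.

    During calibration it emits task-instruction markers from an attached
    schedule; the ``train`` command additionally publishes one
    train-request message, and feedback only starts once a ``model-ready``
    command (normally relayed from the training node) arrives.
    """

    def __init__(self, schedule: StimulusSchedule | None = None,
                 metadata: dict | None = None):
        self.schedule = schedule
        self.state = SessionState("mi", "idle", metadata=metadata or {})
        self._next_stimulus = 0

    def step(self, event):
        """Advance on ``("command", name)`` or ``("tick", dt)``.

        Returns ``(state, emitted)`` where *emitted* is a list of
        :class:`MarkerEvent` and message dicts.
        """
        kind, value = event
        state = self.state
        emitted: list = []
        if kind == "command":
            if value == "pause" and state.phase not in ("idle", "done"):
                state.paused = True
                return state, emitted
            if value == "resume" and state.paused:
                state.paused = False
                return state, emitted
            key = (state.phase, value)
            if key not in MI_COMMANDS:
                raise InvalidCommandError(value, state.phase)
            state.phase = MI_COMMANDS[key]
            emitted.append(_phase_marker(state.clock, state.phase, "mi"))
            if value == "train":
                emitted.append({"type": "message", "topic": "commands",
                                "data": {"cmd": "train"}})
        elif kind == "tick":
            state.clock += value
            if state.phase == "calibration" and not state.paused and self.schedule:
                entries = self.schedule.entries
                while (self._next_stimulus < len(entries)
                       and entries[self._next_stimulus][0] <= state.clock):
                    t, cls = entries[self._next_stimulus]
                    emitted.append(MarkerEvent(t, {"label": cls, "class": cls,
                                                   "phase": "calibration"}))
                    self._next_stimulus += 1
        else:
            raise InvalidArgumentError(f"unknown event kind {kind!r}")
        return state, emitted


def mi_controller_step(controller: MIController, event):
    """Functional alias for :meth:`MIController.step`."""
    return controller.step(event)


@dataclass(frozen=True)
class OddballTimeline:
    """Phase plan of one oddball run.  The defaults schedule
    instructions + 2 x (5 s rest + 35 s stimulus block) = 90 s total."""

    attract: float = 0.0
    instructions: float = 10.0
    rest: float = 5.0
    block_duration: float = 35.0
    n_blocks: int = 2
    stim_rate: float = 3.0
    classes: tuple = (0, 1, 2, 3)
    policy: str = "round-robin"

    @property
    def total_duration(self) -> float:
        return (self.attract + self.instructions
                + self.n_blocks * (self.rest + self.block_duration))

    def phase_plan(self):
        """Ordered (phase, start, duration) triples."""
        plan = []
        t = 0.0
        if self.attract > 0:
            plan.append(("attract", t, self.attract))
            t += self.attract
        plan.append(("instructions", t, self.instructions))
        t += self.instructions
        for _ in range(self.n_blocks):
            plan.append(("rest", t, self.rest))
            t += self.rest
            plan.append(("stimuli", t, self.block_duration))
            t += self.block_duration
        plan.append(("done", t, 0.0))
        return plan

    def n_stimuli_per_block(self) -> int:
        return int(self.block_duration * self.stim_rate)


class OddballController:
    """Tick-driven timeline: every displayed stimulus emits a class-labeled
    marker; rest phases emit none; ticking after ``done`` is a no-op."""

    def __init__(self, timeline: OddballTimeline = OddballTimeline(),
                 seed: int = 0, metadata: dict | None = None):
        self.timeline = timeline
        self.state = SessionState("oddball", "attract", metadata=metadata or {})
        self._plan = timeline.phase_plan()
        self._phase_idx = -1
        per_block = timeline.n_stimuli_per_block()
        blocks = [start for phase, start, _ in self._plan if phase == "stimuli"]
        # one continuous schedule sliced across blocks, so round-robin class
        # counts stay balanced (differ by <= 1) over the whole session
        labels = [c for _, c in make_stimulus_sequence(
            per_block * len(blocks), timeline.classes, timeline.policy,
            timeline.stim_rate, seed).entries]
        self.schedule_entries: list = []
        for b, start in enumerate(blocks):
            for k in range(per_block):
                self.schedule_entries.append(
                    (start + k / timeline.stim_rate, labels[b * per_block + k])
                )
        self._next_stimulus = 0

    def step(self, dt: float):
        """Advance the clock by *dt*; returns ``(state, emitted markers)``."""
        state = self.state
        if state.phase == "done":
            return state, []
        state.clock += dt
        emitted: list = []
        while (self._phase_idx + 1 < len(self._plan)
               and self._plan[self._phase_idx + 1][1] <= state.clock + 1e-12):
            self._phase_idx += 1
            phase = self._plan[self._phase_idx][0]
            state.phase = phase
            emitted.append(_phase_marker(self._plan[self._phase_idx][1], phase,
                                         "oddball"))
            if phase == "done":
                break
        while (self._next_stimulus < len(self.schedule_entries)
               and self.schedule_entries[self._next_stimulus][0] <= state.clock + 1e-12):
            t, cls = self.schedule_entries[self._next_stimulus]
            emitted.append(MarkerEvent(t, {"label": f"stim-{cls}", "class": cls,
                                           "phase": "stimuli"}))
            self._next_stimulus += 1
        return state, emitted


def oddball_controller_step(controller: OddballController, dt: float):
    """Functional alias for :meth:`OddballController.step`."""
    return controller.step(dt)


# ---------------------------------------------------------------------------
# archiving

def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def archive_session(streams, events, path, config: dict | None = None,
                    extra: dict | None = None) -> dict:
    """Write raw streams, events and a re-run manifest under directory *path*.

    *streams* is ``[(StreamInfo, SampleBlock), ...]``; *events* maps a name
    to a marker list.  Everything is written to a temporary directory first
    and moved into place, so an unwritable target leaves no partial
    archive.  Returns the manifest.
    """
    config = dict(config or {})
    manifest = {
        "format": "eegloop-archive-1",
        "config": config,
        "config_digest": config_digest(config),
        "streams": [],
        "events": sorted(events),
        **(extra or {}),
    }
    parent = os.path.dirname(os.path.abspath(path)) or "."
    if not os.path.isdir(parent) or not os.access(parent, os.W_OK):
        raise OSError(f"cannot write archive under {parent!r}")
    tmp = tempfile.mkdtemp(prefix=".archive-", dir=parent)
    try:
        for info, block in streams:
            fname = f"stream-{info.name}.csv"
            write_csv_stream(os.path.join(tmp, fname), info, block)
            manifest["streams"].append({
                "file": fname, "name": info.name, "type": info.stream_type,
                "rate": info.nominal_rate, "labels": list(info.channel_labels),
                "source_id": info.source_id,
            })
        for name, markers in events.items():
            info = StreamInfo(name, "markers", ["payload"], 0)
            write_csv_stream(os.path.join(tmp, f"events-{name}.csv"), info, markers)
        with open(os.path.join(tmp, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        if os.path.isdir(path):
            shutil.rmtree(path)
        os.replace(tmp, path)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return manifest


def load_archive(path):
    """Load ``(manifest, streams, events)`` written by :func:`archive_session`."""
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    streams = []
    for entry in manifest["streams"]:
        info = StreamInfo(entry["name"], entry["type"], entry["labels"],
                          entry["rate"], entry.get("source_id", ""))
        streams.append((info, read_csv_stream(os.path.join(path, entry["file"]), info)))
    events = {}
    for name in manifest["events"]:
        info = StreamInfo(name, "markers", ["payload"], 0)
        events[name] = read_csv_stream(os.path.join(path, f"events-{name}.csv"), info)
    return manifest, streams, events


# ---------------------------------------------------------------------------
# reference applications

@dataclass(frozen=True)
class OddballAppConfig:
    n_classes: int = 4
    n_stimuli: int = 160
    isi: float = 0.3
    target_class: int | None = None  # None: drawn from the seed
    # Window no longer than the ISI (so one evoked response lands in exactly
    # one class's epochs) that still covers the deflection around 0.33 s.
    epoch_window: tuple = (0.15, 0.45)
    mode: str = "avg-then-cov"
    metric: str = "airm"
    shrinkage: float = 0.05
    graph_rate: float = 8.0
    synth: SynthConfig = field(default_factory=SynthConfig)


def _oddball_graph_spec(config: OddballAppConfig) -> dict:
    return {
        "rate": config.graph_rate,
        "epoch_window": list(config.epoch_window),
        "mode": config.mode,
        "metric": config.metric,
        "shrinkage": config.shrinkage,
    }


def _build_oddball_graph(config: OddballAppConfig, eeg: SampleBlock, markers,
                         broker: Broker) -> Graph:
    spec = GraphSpec(
        rate=config.graph_rate,
        name="oddball-calculate",
        nodes=[
            {"id": "eeg", "kind": "block_source", "params": {"block": eeg}},
            {"id": "markers", "kind": "marker_source", "params": {"markers": markers}},
            {"id": "epoch", "kind": "epoch",
             "params": {"t_min": config.epoch_window[0],
                        "t_max": config.epoch_window[1],
                        "fs": config.synth.fs}},
            {"id": "score", "kind": "oddoneout",
             "params": {"class_ids": list(range(config.n_classes)),
                        "mode": config.mode, "metric": config.metric,
                        "shrinkage": config.shrinkage}},
        ],
        edges=[("eeg", "epoch"), ("markers", "epoch:markers"), ("epoch", "score")],
    )
    return Graph(spec, broker=broker)


def _decisions_from_broker(broker: Broker):
    return [
        {"predicted_target": res.predicted_target,
         "probabilities": {str(k): v for k, v in res.probabilities.items()},
         "low_confidence": res.low_confidence}
        for _, res in broker.drain("classification")
    ]


def run_oddball_app(config: OddballAppConfig = OddballAppConfig(),
                    seed: int = 0, out_dir: str | None = None) -> dict:
    """Run one simulated oddball session end to end.

    Generates a synthetic session, streams it through the online graph
    (epoching -> running odd-one-out), optionally archives the raw data,
    and returns the decision trail plus the hidden truth.
    """
    rng = np.random.default_rng(seed)
    target = (config.target_class if config.target_class is not None
              else int(rng.integers(config.n_classes)))
    synth_config = replace(config.synth, seed=seed)
    session = make_oddball_session(config.n_classes, config.n_stimuli, config.isi,
                                   target, synth_config)
    broker = Broker()
    graph = _build_oddball_graph(config, session.eeg, session.markers, broker)
    duration = session.eeg.timestamps[-1] + 1.0
    run_graphs([graph], duration)
    decisions = _decisions_from_broker(broker)
    if not decisions:
        raise EEGLoopError("session produced no classification updates")
    result = {
        "app": "oddball",
        "seed": seed,
        "predicted_target": decisions[-1]["predicted_target"],
        "probabilities": decisions[-1]["probabilities"],
        "decisions": decisions,
        "truth": session.truth,
    }
    if out_dir:
        app_config = {"app": "oddball", "seed": seed,
                      "n_classes": config.n_classes,
                      "n_stimuli": config.n_stimuli, "isi": config.isi,
                      "graph": _oddball_graph_spec(config),
                      "synth": asdict(synth_config)}
        archive_session(
            streams=[(synth_config.stream_info(), session.eeg)],
            events={"markers": session.markers},
            path=out_dir,
            config=app_config,
            extra={"decisions": decisions,
                   "truth": {"target_class": session.truth["target_class"]}},
        )
    return result


def replay_oddball(archive_dir: str) -> list:
    """Re-run the archived oddball pipeline offline; returns the decision
    trail, which must match the archived online decisions bit-identically."""
    manifest, streams, events = load_archive(archive_dir)
    cfg = manifest["config"]
    graph_cfg = cfg["graph"]
    synth_cfg = SynthConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in cfg["synth"].items()})
    config = OddballAppConfig(
        n_classes=cfg["n_classes"], n_stimuli=cfg["n_stimuli"], isi=cfg["isi"],
        epoch_window=tuple(graph_cfg["epoch_window"]), mode=graph_cfg["mode"],
        metric=graph_cfg["metric"], shrinkage=graph_cfg["shrinkage"],
        graph_rate=graph_cfg["rate"], synth=synth_cfg,
    )
    (info, eeg), = streams
    markers = events["markers"]
    broker = Broker()
    graph = _build_oddball_graph(config, eeg, markers, broker)
    run_graphs([graph], eeg.timestamps[-1] + 1.0)
    return _decisions_from_broker(broker)


@dataclass(frozen=True)
class MIAppConfig:
    n_train_per_class: int = 20
    n_test_per_class: int = 20
    epoch_duration: float = 2.0
    class_covs: tuple | None = None  # None: ERD pair from synth defaults
    metric: str = "airm"
    shrinkage: float = 0.05
    synth: SynthConfig = field(default_factory=SynthConfig)


def run_mi_app(config: MIAppConfig = MIAppConfig(), seed: int = 0,
               out_dir: str | None = None) -> dict:
    """Run a simulated motor-imagery session: calibration epochs train an
    MDM model, a held-out feedback session is classified, and the state
    machine walks idle -> calibration -> training -> feedback -> done."""
    from .riemann import CovSpec, mdm_accuracy, mdm_fit
    from .synth import make_erd_covs

    synth_train = replace(config.synth, seed=seed)
    synth_test = replace(config.synth, seed=seed + 1)
    covs = (list(config.class_covs) if config.class_covs is not None
            else make_erd_covs(config.synth.n_channels, config.synth.erd_attenuation))

    controller = MIController(metadata={"seed": seed})
    log: list = []
    _, em = controller.step(("command", "start"))
    log += em
    train = make_mi_session(config.n_train_per_class, covs, synth_train,
                            config.epoch_duration)
    spec = EpochSpec(0.0, config.epoch_duration)
    train_epochs, _ = epoch_timelocked(train.eeg, train.markers, spec,
                                       fs=synth_train.fs)
    _, em = controller.step(("command", "train"))
    log += em
    model = mdm_fit(train_epochs, CovSpec(shrinkage=config.shrinkage),
                    metric=config.metric,
                    provenance={"seed": seed, "epoch_duration": config.epoch_duration})
    _, em = controller.step(("command", "model-ready"))
    log += em
    test = make_mi_session(config.n_test_per_class, covs, synth_test,
                           config.epoch_duration)
    test_epochs, _ = epoch_timelocked(test.eeg, test.markers, spec,
                                      fs=synth_test.fs)
    accuracy = mdm_accuracy(model, test_epochs)
    _, em = controller.step(("command", "stop"))
    log += em

    result = {"app": "mi", "seed": seed, "accuracy": accuracy,
              "phase": controller.state.phase,
              "n_train": len(train_epochs), "n_test": len(test_epochs)}
    if out_dir:
        app_config = {"app": "mi", "seed": seed,
                      "epoch_duration": config.epoch_duration,
                      "metric": config.metric, "shrinkage": config.shrinkage,
                      "synth": asdict(synth_train)}
        markers = [m for m in log if isinstance(m, MarkerEvent)]
        archive_session(
            streams=[(synth_train.stream_info("mi-calibration"), train.eeg),
                     (synth_test.stream_info("mi-feedback"), test.eeg)],
            events={"markers": train.markers + test.markers,
                    "state-log": markers},
            path=out_dir, config=app_config,
            extra={"accuracy": accuracy},
        )
    return result


# ---------------------------------------------------------------------------
# graph configuration files

def load_graph_config(path) -> list:
    """Load a YAML application file: a list of graphs, each with ``rate``,
    ``nodes`` (id/kind/params) and ``edges`` (source/target, port after a
    colon).  Returns a list of :class:`GraphSpec`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    graphs = doc.get("graphs", doc) if isinstance(doc, dict) else doc
    specs = []
    for g in graphs:
        specs.append(GraphSpec(
            rate=g["rate"],
            name=g.get("name", "graph"),
            nodes=[{"id": n["id"], "kind": n["kind"],
                    "params": n.get("params", {})} for n in g.get("nodes", [])],
            edges=[(e["source"], e["target"]) for e in g.get("edges", [])],
        ))
    return specs
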