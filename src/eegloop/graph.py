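"""Rate-scheduled acyclic processing graphs.

An application is a set of graphs.  Each graph executes all of its nodes
once per *tick*, in a topological order of the edge relation, at a fixed
rate on a simulated session clock.  Outputs produced during a tick are
visible to downstream nodes within the same tick.  Graphs communicate
asynchronously through a shared :class:`~eegloop.broker.Broker`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .broker import Broker
from .errors import GraphCycleError, GraphTickError, InvalidArgumentError, InvalidSpecError

DEFAULT_IN = "in"
DEFAULT_OUT = "out"


@dataclass(frozen=True)
class NodeSpec:
    id: str
    kind: str
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class EdgeSpec:
    """Directed edge ``source_node:source_port -> target_node:target_port``."""

    source: str
    target: str
    source_port: str = DEFAULT_OUT
    target_port: str = DEFAULT_IN

    @classmethod
    def parse(cls, source: str, target: str) -> "EdgeSpec":
        """Parse ``"node"`` or ``"node:port"`` endpoint strings."""
        src, _, sport = source.partition(":")
        dst, _, dport = target.partition(":")
        return cls(src, dst, sport or DEFAULT_OUT, dport or DEFAULT_IN)


@dataclass
class GraphSpec:
    """Declarative description of one processing graph."""

    rate: float
    nodes: list
    edges: list
    name: str = "graph"

    def __post_init__(self):
        if not self.rate > 0:
            raise InvalidArgumentError("graph rate must be positive")
        self.nodes = [n if isinstance(n, NodeSpec) else NodeSpec(**n) for n in self.nodes]
        parsed = []
        for e in self.edges:
            if isinstance(e, EdgeSpec):
                parsed.append(e)
            elif isinstance(e, dict):
                parsed.append(EdgeSpec.parse(e["source"], e["target"]))
            else:
                parsed.append(EdgeSpec.parse(*e))
        self.edges = parsed


def _find_cycle(adjacency: dict) -> list:
    """Return one directed cycle as a node-id list (last element repeats first)."""
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {n: WHITE for n in adjacency}
    stack: list[str] = []

    def visit(node):
        color[node] = GRAY
        stack.append(node)
        for succ in adjacency[node]:
            if color[succ] == GRAY:
                return stack[stack.index(succ):] + [succ]
            if color[succ] == WHITE:
                found = visit(succ)
                if found:
                    return found
        stack.pop()
        color[node] = BLACK
        return None

    for start in adjacency:
        if color[start] == WHITE:
            found = visit(start)
            if found:
                return found
    raise AssertionError("no cycle found")  # pragma: no cover


def validate_graph(spec: GraphSpec) -> list:
    """Validate *spec* and return a topological order of its node ids.

    The order is deterministic (Kahn's algorithm with ties broken by
    declaration order), so re-validation of the same spec returns the
    same order.

    Raises
    ------
    InvalidSpecError
        Duplicate node ids or an edge endpoint that names no node.
    GraphCycleError
        The edge relation has a cycle; one offending cycle is reported.
    """
    ids = [n.id for n in spec.nodes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InvalidSpecError(f"duplicate node ids: {dupes}")
    known = set(ids)
    for e in spec.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in known:
                raise InvalidSpecError(f"edge endpoint {endpoint!r} names no node")

    position = {node_id: i for i, node_id in enumerate(ids)}
    successors = {node_id: [] for node_id in ids}
    in_degree = {node_id: 0 for node_id in ids}
    for e in spec.edges:
        successors[e.source].append(e.target)
        in_degree[e.target] += 1

    ready = sorted((n for n in ids if in_degree[n] == 0), key=position.__getitem__)
    order = []
    while ready:
        node = ready.pop(0)
        order.append(node)
        changed = False
        for succ in successors[node]:
            in_degree[succ] -= 1
            if in_degree[succ] == 0:
                ready.append(succ)
                changed = True
        if changed:
            ready.sort(key=position.__getitem__)
    if len(order) != len(ids):
        raise GraphCycleError(_find_cycle(successors))
    return order


class Node:
    """Base class for graph nodes.

    Subclasses implement :meth:`update`, reading ``self.inputs`` (a dict
    port -> value, populated for the current tick) and writing
    ``self.outputs``.  ``self.clock`` holds the simulated time (s) of the
    current tick and ``self.broker`` the shared broker, when attached.
    """

    def __init__(self, **params):
        self.params = params
        self.inputs: dict = {}
        self.outputs: dict = {}
        self.clock: float = 0.0
        self.broker: Broker | None = None

    def setup(self) -> None:
        """Hook called once after the runtime graph is assembled."""

    def update(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


NODE_REGISTRY: dict[str, type] = {}


def register_node(kind: str):
    """Class decorator registering a node class under *kind* for graph specs."""

    def wrap(cls):
        if not issubclass(cls, Node):
            raise InvalidArgumentError(f"{cls!r} is not a Node subclass")
        NODE_REGISTRY[kind] = cls
        return cls

    return wrap


class Graph:
    """Runtime instantiation of a :class:`GraphSpec`."""

    def __init__(self, spec: GraphSpec, broker: Broker | None = None, registry=None):
        registry = registry if registry is not None else NODE_REGISTRY
        self.spec = spec
        self.order = validate_graph(spec)
        self.broker = broker
        self.nodes: dict[str, Node] = {}
        for nspec in spec.nodes:
            if nspec.kind not in registry:
                raise InvalidSpecError(f"unknown node kind {nspec.kind!r}")
            node = registry[nspec.kind](**nspec.params)
            node.broker = broker
            self.nodes[nspec.id] = node
        self._in_edges: dict[str, list] = {n: [] for n in self.nodes}
        for e in spec.edges:
            self._in_edges[e.target].append(e)
        for node in self.nodes.values():
            node.setup()
        self.tick_count = 0
        self.clock = 0.0

    def tick(self, clock: float | None = None) -> None:
        """Run one tick: every node updated exactly once, in topological order.

        A node failure aborts the tick with the node id attached; nodes
        after the failing one are not updated that tick.
        """
        if clock is not None:
            self.clock = clock
        for node_id in self.order:
            node = self.nodes[node_id]
            node.inputs = {}
            for e in self._in_edges[node_id]:
                value = self.nodes[e.source].outputs.get(e.source_port)
                if value is not None:
                    node.inputs[e.target_port] = value
            node.outputs = {}
            node.clock = self.clock
            try:
                node.update()
            except Exception as exc:
                raise GraphTickError(node_id, exc) from exc
        self.tick_count += 1


def tick_graph(graph: Graph, clock: float | None = None) -> None:
    """Functional alias for :meth:`Graph.tick`."""
    graph.tick(clock)


def run_graphs(graphs, duration: float) -> None:
    """Drive one or more graphs for *duration* seconds of simulated time.

    A graph at rate ``r`` ticks exactly ``floor(duration * r)`` times, at
    simulated instants ``k / r``.  No wall-clock dependence: ticks are
    executed in order of simulated time, ties broken by graph position in
    *graphs* (so a broker graph listed first drains before consumers).
    """
    if duration < 0:
        raise InvalidArgumentError("duration must be nonnegative")
    events = []
    for gi, g in enumerate(graphs):
        n_ticks = int(duration * g.spec.rate + 1e-9)
        for k in range(1, n_ticks + 1):
            events.append((k / g.spec.rate, gi, g))
    events.sort(key=lambda item: (item[0], item[1]))
    for t, _, g in events:
        g.tick(clock=t)
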