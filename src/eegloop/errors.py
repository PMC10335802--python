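"""Exception hierarchy shared across the package."""


class EEGLoopError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EEGLoopError, ValueError):
    """A caller-supplied value violates a documented precondition."""


class InvalidSpecError(EEGLoopError):
    """A graph specification is malformed (dangling edge, duplicate id, ...)."""


class GraphCycleError(InvalidSpecError):
    """The edge relation of a graph specification contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("graph contains a cycle: " + " -> ".join(self.cycle))


class GraphTickError(EEGLoopError):
    """A node raised during ``update()``; the offending node id is attached."""

    def __init__(self, node_id, cause):
        self.node_id = node_id
        super().__init__(f"node {node_id!r} failed during tick: {cause}")


class FilterStateError(EEGLoopError):
    """Streaming filter state is inconsistent with the incoming block."""


class FormatError(EEGLoopError):
    """A file on disk is not in the expected format."""

    def __init__(self, message, offset=None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at byte offset {offset})"
        super().__init__(message)


class VersionError(FormatError):
    """A persisted artifact was written by an incompatible format version."""

    def __init__(self, message):
        super().__init__(message, offset=None)


class NumericalError(EEGLoopError):
    """A numerical routine hit a singular or otherwise degenerate input."""


class ConvergenceError(NumericalError):
    """An iterative solver did not reach its tolerance."""

    def __init__(self, message, residual=None):
        self.residual = residual
        super().__init__(message)


class EstimationError(EEGLoopError):
    """An estimator could not produce a result (e.g. zero usable pairs)."""


class InvalidCommandError(EEGLoopError):
    """A session command is not legal in the current phase."""

    def __init__(self, command, phase):
        self.command = command
        self.phase = phase
        super().__init__(f"command {command!r} is not valid in phase {phase!r}")
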