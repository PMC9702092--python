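"""Exception hierarchy for reconstruction validation and analysis errors."""


class DendroquantError(Exception):
    """Base class for all package errors."""


class SWCParseError(DendroquantError):
    """A line of an SWC file could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(DendroquantError):
    """A reconstruction violates a structural invariant (duplicate ids, bad codes...)."""


class TopologyError(ValidationError):
    """Orphan parent reference, missing/multiple roots, or a cycle in the parent relation."""


class ChannelJoinError(ValidationError):
    """A channel-table row references a node absent from the reconstruction."""


class DegenerateGeometryError(DendroquantError):
    """A compartment has coincident endpoints (zero length)."""

    def __init__(self, node_ids):
        self.node_ids = list(node_ids)
        super().__init__(
            f"degenerate (zero-length) compartments at child nodes: {self.node_ids}"
        )


class NormalizationError(DendroquantError):
    """Cohort normalization is impossible (zero control mean) or already applied."""


class ParameterError(DendroquantError):
    """An analysis parameter is out of its valid range."""


class FitError(DendroquantError):
    """Too few usable points to fit a model."""


class GenerationError(DendroquantError):
    """The synthetic generator could not satisfy its spec within bounded retries."""
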