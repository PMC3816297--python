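"""Exception hierarchy for provenance-graph construction and persistence."""


class ProvenanceError(Exception):
    """Base class for all provgraph errors."""


class StructuralError(ProvenanceError):
    """A creation-time or save-time structural rule was breached.

    ``violations`` carries the :class:`~provgraph.validation.Violation`
    records when the error was raised by the persistence layer; it is empty
    for creation-time rejections, whose message names the rule directly.
    """

    def __init__(self, message, violations=()):
        super().__init__(message)
        self.violations = list(violations)


class TemporalError(ProvenanceError):
    """A time-window rule was breached at creation time."""


class SchemaError(ProvenanceError):
    """An XML document does not conform to the account dialect."""
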