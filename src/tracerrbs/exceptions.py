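"""Exception hierarchy for the trace-rrbs toolkit."""


class TraceRRBSError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(TraceRRBSError, ValueError):
    """Raised for malformed user input (sequences, files, reads)."""


class InvalidParameterError(TraceRRBSError, ValueError):
    """Raised for out-of-range or inconsistent configuration parameters."""


class InternalConsistencyError(TraceRRBSError, RuntimeError):
    """Raised when internal metadata disagrees (indicates a bug, not bad input)."""
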