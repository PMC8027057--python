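"""Exception types shared across the pipeline."""


class SyntronetError(Exception):
    """Base class for all package errors."""


class ParameterError(SyntronetError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(SyntronetError, ValueError):
    """A file does not conform to the expected on-disk layout."""


class GenerationError(SyntronetError, ValueError):
    """A synthetic-data request is internally inconsistent (e.g. overlapping ROIs)."""


class DegenerateDataError(SyntronetError, ValueError):
    """Input data admit no well-defined estimate (all-zero rows, zero variance...)."""


class ConvergenceError(SyntronetError, RuntimeError):
    """An iterative solver exhausted its budget without meeting tolerance."""
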