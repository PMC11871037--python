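"""Exception hierarchy shared across the package."""


class TraceGTTError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TraceGTTError):
    """Invalid configuration: bad group-effect keys, atom counts, windows."""


class SchemaError(TraceGTTError):
    """Misaligned, duplicated, or otherwise malformed input tables."""


class DomainError(TraceGTTError):
    """Input values outside the mathematical domain of an operation."""


class NumericalError(TraceGTTError):
    """Ill-conditioned or unstable numerical computation."""


class InsufficientDataError(TraceGTTError):
    """Too few observations (or dams) for the requested analysis."""
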