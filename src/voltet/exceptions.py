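"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`VoltetError`,
so callers (and the CLI) can distinguish user/data problems from genuine bugs.
"""


class VoltetError(Exception):
    """Base class for all errors raised deliberately by voltet."""


class InvalidGridError(VoltetError):
    """Potential grid parameters cannot form a valid triangular sweep."""


class DomainError(VoltetError):
    """A numeric argument lies outside its physically meaningful domain."""


class ShapeError(VoltetError):
    """An array argument has the wrong shape or length."""


class ConfigurationError(VoltetError):
    """Inconsistent or unusable configuration (duplicate sensors, bad paths...)."""


class RegistryError(VoltetError):
    """Lookup of an unknown registered name (transfer function, fixture...)."""


class DecompositionError(VoltetError):
    """Signal cannot be wavelet-decomposed at the requested depth."""


class DataError(VoltetError):
    """Training/evaluation data are unusable (non-finite, too few rows...)."""


class SchemaError(VoltetError):
    """An external CSV/YAML file violates the documented schema."""


class ProtocolError(VoltetError):
    """Evaluation protocol violated (e.g. overlapping train/test subsets)."""


class DiagnosticError(VoltetError):
    """A diagnostic (PCA complementarity) cannot be computed as requested."""
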