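"""Typed exceptions shared across the pipeline.

Validation is total: every malformed input raises one of these, never a
silent coercion.
"""


class MPEImmuneError(Exception):
    """Base class for all package errors."""


class FormatError(MPEImmuneError):
    """A file does not match the expected table layout."""


class IntegrityError(MPEImmuneError):
    """A table violates a structural invariant (e.g. duplicate probe ids)."""


class NormalizationError(MPEImmuneError):
    """Control probes are missing or unusable for normalization."""


class ConfigError(MPEImmuneError):
    """A configuration object or file is invalid."""


class ConvergenceError(MPEImmuneError):
    """An iterative fit failed to converge."""
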