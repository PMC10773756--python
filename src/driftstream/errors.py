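"""Exception hierarchy shared across the package."""


class DriftStreamError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DriftStreamError, ValueError):
    """Malformed input data: ragged rows, shape mismatches, bad labels."""


class ConfigurationError(DriftStreamError, ValueError):
    """Invalid configuration values (window sizes, bin counts, dims...)."""


class StateError(DriftStreamError, RuntimeError):
    """A pipeline component was used before it was fitted/trained."""
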