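"""Exception types shared across the package."""


class VultureNetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VultureNetError):
    """A config file, column mapping, or parameter set is unusable."""


class EmptyInputError(VultureNetError):
    """An input table or file contains no usable records."""


class ConsistencyError(VultureNetError):
    """An internal invariant was violated (e.g. together > joint sampled)."""
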