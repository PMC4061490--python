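"""Exception types shared across the package."""


class EegperfError(Exception):
    """Base class for package errors."""


class ConfigurationError(EegperfError, ValueError):
    """Inputs are inconsistent with the requested configuration
    (e.g. a referenced channel label does not exist)."""


class ParameterError(EegperfError, ValueError):
    """A numeric parameter is outside its valid range."""


class DataError(EegperfError, ValueError):
    """Input data violate a structural precondition (empty, too short,
    constant where variation is required, ...)."""
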