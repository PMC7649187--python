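"""Exception types shared across the package."""


class TacbError(Exception):
    """Base class for all package errors."""


class ValidationError(TacbError, ValueError):
    """Input data failed validation (non-finite samples, bad shapes, ...)."""


class ConfigurationError(TacbError, ValueError):
    """A configuration is internally inconsistent or incompatible with the data."""


class FrequencyError(TacbError, ValueError):
    """A requested frequency cannot be represented (e.g. above Nyquist)."""


class DegenerateNullError(TacbError, ValueError):
    """The surrogate ensemble is degenerate (all-zero), no null can be fitted."""


class GridError(TacbError, ValueError):
    """A stencil offset is not representable on the frequency grid."""


class FormatError(TacbError, ValueError):
    """An input file could not be parsed."""
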