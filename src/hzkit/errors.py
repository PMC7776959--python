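"""Exception hierarchy shared across hzkit modules."""


class HzkitError(Exception):
    """Base class for all hzkit errors."""


class FormatError(HzkitError):
    """A file could not be parsed in the declared format."""


class ValidationError(HzkitError):
    """Input data violated a documented invariant."""


class ConfigurationError(HzkitError):
    """A configuration value is invalid or inconsistent."""


class EstimationError(HzkitError):
    """An estimator could not produce a result (e.g. no usable data)."""


class FitError(HzkitError):
    """A model fit failed to converge."""


class ContractError(HzkitError):
    """An internal API contract was violated by the caller."""
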