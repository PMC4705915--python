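"""Exception hierarchy shared across the package.

All package errors derive from :class:`CvreactError` so callers (and the
CLI) can separate validation problems (exit code 2) from genuine bugs.
"""


class CvreactError(Exception):
    """Base class for all cvreact errors."""


class ConfigurationError(CvreactError):
    """A scenario or pipeline configuration field is invalid."""


class ValidationError(CvreactError):
    """Input data violate a documented precondition or sanity gate."""


class FormatError(CvreactError):
    """A file does not conform to the expected text format."""
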