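"""Exception hierarchy for hiftload.

All errors raised on purpose by this package derive from
:class:`HiftLoadError`, so callers can catch one base class at pipeline
boundaries while still distinguishing configuration problems from data
problems.
"""


class HiftLoadError(Exception):
    """Base class for all hiftload errors."""


class ConfigurationError(HiftLoadError, ValueError):
    """A configuration value is invalid; the message names the field."""


class ValidationError(HiftLoadError, ValueError):
    """An input value violates a documented precondition."""


class FormatError(HiftLoadError, ValueError):
    """A file is structurally malformed (e.g. a required column is missing)."""


class IntegrityError(HiftLoadError, ValueError):
    """Referential or uniqueness integrity is violated (unknown participant,
    duplicate session key)."""
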