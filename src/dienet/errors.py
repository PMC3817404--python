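"""Typed exceptions raised across the package.

Readers and validators never silently coerce: malformed input raises a
:class:`FormatError` or :class:`IntegrityError` naming the offending row or
column, and invalid configuration raises a :class:`ConfigError` before any
computation starts.
"""


class DienetError(Exception):
    """Base class for all package errors."""


class FormatError(DienetError):
    """A file or table does not conform to the expected layout or dtypes."""


class IntegrityError(DienetError):
    """Data is well-formed but internally inconsistent (duplicates, orphans)."""


class ConfigError(DienetError):
    """A configuration value violates its documented constraints."""


class AnalysisError(DienetError):
    """A computation cannot proceed on the given data (degenerate input)."""
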