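"""Exception hierarchy shared across the package."""


class PairedConcordError(Exception):
    """Base class for all package errors."""


class ParseError(PairedConcordError):
    """A file could not be parsed; message names the offending row/column."""


class SchemaError(PairedConcordError):
    """A table is missing required columns or has an invalid layout."""


class ValidationError(PairedConcordError):
    """A domain-type invariant is violated."""


class DomainError(PairedConcordError):
    """An operation was applied to values outside its mathematical domain."""


class InsufficientDataError(PairedConcordError):
    """Too few pairs/samples for the requested statistic."""


class CoverageError(PairedConcordError):
    """Too few classifier genes matched in the expression matrix."""


class NotBundledError(PairedConcordError):
    """A named resource is not shipped with the package and must be supplied."""


class ConfigError(PairedConcordError):
    """Invalid configuration values."""
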