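"""Exception hierarchy shared across the package.

Every data-validation failure raises a subclass of :class:`DelimixError`
so callers (and the CLI) can map problems onto exit codes without
string-matching messages.
"""


class DelimixError(ValueError):
    """Base class for all delimix validation and analysis errors."""


class FormatError(DelimixError):
    """A file or table is structurally malformed (ragged rows, bad tokens)."""


class AlignmentError(FormatError):
    """Sequences in an alignment violate alignment invariants."""


class IdError(DelimixError):
    """Specimen/locus identifiers are duplicated, missing, or unjoinable."""


class BoundsError(DelimixError):
    """A value lies outside its documented domain (coordinates, fractions)."""


class SchemaError(DelimixError):
    """A table is missing required columns or has the wrong column count."""


class DomainError(DelimixError):
    """A numeric input violates a mathematical precondition (e.g. log of <= 0)."""


class DegenerateInputError(DelimixError):
    """Input is too degenerate for the requested analysis (constant column etc.)."""


class SingularFitError(DelimixError):
    """A mixture component collapsed despite covariance regularization."""


class SelectionError(DelimixError):
    """Model selection failed for every candidate in the search grid."""


class ConfigError(DelimixError):
    """A run configuration is incomplete or inconsistent."""
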