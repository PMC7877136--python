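"""Exception hierarchy.

``SchemaError`` and ``CodeValidationError`` signal problems with the
*shape* and *content* of input tables; ``InstrumentFormatError`` signals a
file that cannot be parsed at all; ``EmptyAnalysisError`` signals a
statistical degeneracy (e.g. list-wise deletion removed every record).
The CLI maps these onto distinct exit codes.
"""


class InterraiCiError(Exception):
    """Base class for all package errors."""


class InstrumentFormatError(InterraiCiError):
    """The file could not be parsed in the named format."""


class SchemaError(InterraiCiError):
    """Unknown / absent columns or keys; the message names the offenders."""


class CodeValidationError(InterraiCiError):
    """A cell value violates the coding dictionary; names subject and item."""


class UnknownRuleError(InterraiCiError, KeyError):
    """A rule id outside the shipped 26-rule catalogue."""


class EmptyAnalysisError(InterraiCiError):
    """An analysis set is empty after deletion; never silently ignored."""
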