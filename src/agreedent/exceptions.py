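"""Exception hierarchy for agreedent."""


class AgreedentError(Exception):
    """Base class for all package errors."""


class SchemaError(AgreedentError):
    """A required column or field is missing from an input file."""


class ValidationError(AgreedentError):
    """A record carries a value that is invalid under its staging scheme."""


class DuplicateRecordError(AgreedentError):
    """The same (subject, observer, session, tooth, method) key appears twice."""


class EmptySelectionError(AgreedentError):
    """A filter (method, teeth, session) selected no records."""


class IncompleteDesignError(AgreedentError):
    """An observer is missing one of the two rating sessions."""


class InsufficientDataError(AgreedentError):
    """Too few informative units/pairs to estimate a coefficient."""


class DegenerateAlphabetError(AgreedentError):
    """A weight matrix was requested on fewer than two categories."""


class CalibrationError(AgreedentError):
    """The requested agreement level cannot be reached by any correlation."""
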