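"""Exception hierarchy for ilsom."""


class IlsomError(Exception):
    """Base class for all ilsom errors."""


class FormatError(IlsomError):
    """A text input file violates the documented layout."""


class NamingError(IlsomError):
    """A file name does not follow the dataset naming convention."""


class ConsistencyError(IlsomError):
    """Companion files disagree with the main dataset (dimensions, labels)."""


class NormalizationError(IlsomError):
    """A pattern cannot be unit-normalized (all-zero or all-missing)."""
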