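"""Exception hierarchy for the diagnosis grammar engine."""


class UDSError(Exception):
    """Base class for all engine errors."""


class LexiconError(UDSError):
    """Malformed lexicon file (bad column count, unknown category, ...)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateEntryError(LexiconError):
    """A (surface, category, subcategory) triple occurs more than once."""


class UnknownSlotError(UDSError):
    """An identifier not recognized by the binding grammar."""


class CategoryError(UDSError):
    """A surface bound to a slot whose category it does not belong to."""


class EmptyDiagnosisError(UDSError):
    """Every component of the binding is empty."""


class InvalidDiagnosisError(UDSError):
    """Only the etiology is set; etiological agents alone are not diagnoses."""


class TemplateError(UDSError):
    """A pathogenesis template is missing one of its required slots."""


class ChainError(UDSError):
    """Diagnosis chaining called without effects."""
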