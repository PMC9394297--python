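"""Exception hierarchy for the isobolab pipeline."""


class IsobolabError(Exception):
    """Base class for all package errors."""


class ValidationError(IsobolabError):
    """A domain object or input table violates an invariant.

    Carries optional row context (``context``) so file-level errors can
    name the offending row.
    """

    def __init__(self, message: str, context: object = None):
        if context is not None:
            message = f"{message} (context: {context})"
        super().__init__(message)
        self.context = context


class ComputationError(IsobolabError):
    """A computation is undefined for the given inputs (e.g. zero slope)."""
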