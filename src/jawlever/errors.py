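"""Exception hierarchy for the jaw-lever model."""


class JawLeverError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(JawLeverError, ValueError):
    """A scalar input violates its physical domain (e.g. non-positive mass)."""


class SchemaError(JawLeverError, ValueError):
    """An input file does not conform to the expected tabular schema."""


class DegenerateGeometryError(JawLeverError):
    """Landmark configuration from which an action line cannot be derived.

    Raised e.g. for a purely mediolateral muscle pull (zero sagittal
    projection) or an insertion whose sagittal position coincides with
    the condyle (zero lever arm, undefined angle theta).
    """

    def __init__(self, muscle: str, reason: str, gape: float | None = None):
        self.muscle = muscle
        self.reason = reason
        self.gape = gape
        at = f" at gape {gape:g} deg" if gape is not None else ""
        super().__init__(f"degenerate geometry for muscle {muscle!r}{at}: {reason}")


class ModelError(JawLeverError):
    """The model cannot be evaluated (e.g. no jaw-closing muscle remains)."""
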