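"""Exception hierarchy shared across the package."""


class FlimsortError(Exception):
    """Base class for all flimsort errors."""


class DomainError(FlimsortError, ValueError):
    """An input value lies outside the physically meaningful domain."""


class InvalidPhaseError(DomainError):
    """Phase shift outside [0, pi/2): non-physical for a single-exponential decay."""


class FormatError(FlimsortError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(FlimsortError, ValueError):
    """A domain object violates one of its invariants."""


class DegenerateRangeError(ValidationError):
    """A lifetime acceptance window would have zero width."""


class StageError(FlimsortError, RuntimeError):
    """A classification-pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
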