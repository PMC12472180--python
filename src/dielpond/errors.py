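"""Exception hierarchy shared across the package."""


class DielPondError(Exception):
    """Base class for all package errors."""


class ValidationError(DielPondError, ValueError):
    """An input table or record violates a structural invariant."""


class DomainError(DielPondError, ValueError):
    """A numeric argument lies outside its physical domain."""


class FitInfeasibleError(DielPondError):
    """Too few usable observations to fit the requested model."""


class MissingTreatmentError(DielPondError, KeyError):
    """An incubation treatment required by the partitioning equations is absent."""

    def __init__(self, label: str):
        super().__init__(label)
        self.label = label

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"required treatment {self.label!r} is missing from the experiment"
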