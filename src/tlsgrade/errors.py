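"""Exception hierarchy shared across the pipeline stages."""


class TLSGradeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TLSGradeError):
    """An invalid or internally inconsistent configuration."""


class ValidationError(TLSGradeError):
    """Input tables violate the documented schemas or referential integrity.

    ``problems`` carries one human-readable message per violation so callers
    can report every issue at once instead of failing on the first.
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        super().__init__(message)
        self.problems = problems or []

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.problems:
            return base + "\n  - " + "\n  - ".join(self.problems)
        return base


class DegenerateRegionError(TLSGradeError):
    """A region with zero nucleated cells; proportions are undefined."""


class NoCutpointError(TLSGradeError):
    """No admissible cutoff exists (constant feature or minprop too strict)."""


class UndefinedStatisticError(TLSGradeError):
    """A test statistic is undefined for the given data (e.g. no events)."""
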