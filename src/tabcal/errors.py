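"""Exception hierarchy for tabcal."""


class TabcalError(Exception):
    """Base class for all tabcal errors."""


class InvalidGeometryError(TabcalError):
    """Tablet geometry (diameter/thickness) is non-positive."""


class InfeasibleRecipeError(TabcalError):
    """Recipe leaves no mass for the excipient base."""


class InfeasibleConstraintsError(TabcalError):
    """Mixture constraint region is empty or degenerate."""


class DomainError(TabcalError):
    """Composition lies outside the designed constraint region."""


class RankDeficiencyError(TabcalError):
    """Training compositions are collinear or otherwise degenerate."""


class SingularFitError(TabcalError):
    """Calibration anchors do not determine a unique fit."""


class UndefinedStatisticError(TabcalError):
    """A statistic is undefined for the given sample (e.g. zero variance)."""


class ValidationError(TabcalError):
    """Input table failed validation.

    Carries optional ``row`` and ``column`` context so the offending cell
    can be named in the message.
    """

    def __init__(self, message: str, row=None, column=None):
        ctx = []
        if row is not None:
            ctx.append(f"row {row}")
        if column is not None:
            ctx.append(f"column {column!r}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.row = row
        self.column = column
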