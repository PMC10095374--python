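"""Exception hierarchy shared across the package."""


class MrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrError):
    """A required column, option or resource is missing or inconsistent."""


class RowValidationError(MrError):
    """One or more input rows failed field validation.

    ``rows`` maps 1-based data-row numbers to a description of the failure.
    """

    def __init__(self, rows: dict):
        self.rows = dict(rows)
        detail = "; ".join(f"row {i}: {msg}" for i, msg in sorted(self.rows.items()))
        super().__init__(f"{len(self.rows)} row(s) failed validation: {detail}")


class InsufficientInstrumentsError(MrError):
    """Too few instruments for the requested estimator."""


class DegenerateInstrumentError(MrError):
    """An instrument cannot yield a Wald ratio (zero exposure effect)."""


class InfeasibleScenarioError(MrError):
    """A simulation scenario cannot plausibly produce the requested instruments."""
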