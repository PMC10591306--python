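"""Exception hierarchy shared across the package.

Structural faults found by plan checking are *returned* (see
:mod:`wardflow.plan`), not raised; everything here signals a runtime
contract violation.
"""


class WardflowError(Exception):
    """Base class for all wardflow errors."""


class MissingField(WardflowError):
    """A required field is absent from a record (no default available)."""

    def __init__(self, name: str, message: str | None = None):
        self.name = name
        super().__init__(message or f"required field missing: {name!r}")


class InvalidValue(WardflowError):
    """A value cannot be coerced to its declared kind or violates its range."""

    def __init__(self, name: str, reason: str):
        self.name = name
        self.reason = reason
        super().__init__(f"invalid value for {name!r}: {reason}")


class SchemaMismatch(WardflowError):
    """Schema/version/dimension disagreement between components."""


class DegenerateLabels(WardflowError):
    """Labelled data contains a single class; ROC AUC is undefined."""


class InsufficientSamples(WardflowError):
    """Too few perturbation samples to fit a local surrogate."""


class NoSeverityRecorded(WardflowError):
    """A journey carries no severity result to take a maximum over."""


class ConfigInfeasible(WardflowError):
    """A simulation configuration cannot produce the requested cohort."""


class InconsistentJourney(WardflowError):
    """A journey references steps or transitions absent from its plan."""


class NoBreakdown(WardflowError):
    """An algorithm result carries no per-factor breakdown to render."""


class MissingMetric(WardflowError):
    """Model metadata is incomplete for the requested panel."""
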