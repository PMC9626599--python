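"""Typed exceptions shared across pipeline stages."""


class SegmetalsError(Exception):
    """Base class for all package errors."""


class InvalidScenarioError(SegmetalsError, ValueError):
    """A synthetic scenario violates its own invariants."""


class ConfigurationError(SegmetalsError, ValueError):
    """An unknown label, strategy, or malformed configuration value."""


class InsufficientDataError(SegmetalsError, ValueError):
    """A required stratum, category, or sample is empty or too small."""


class DomainError(SegmetalsError, ValueError):
    """An input is outside the mathematical domain of the operation."""


class UnitError(SegmetalsError, ValueError):
    """Incompatible measurement units without harmonization metadata."""


class CountyExcludedSignal(SegmetalsError):
    """A county is excluded by rule (e.g. single census tract).

    Distinct from a failure: callers iterating over counties catch this and
    tabulate the exclusion.
    """

    def __init__(self, county_id: str, reason: str):
        self.county_id = county_id
        self.reason = reason
        super().__init__(f"county {county_id} excluded: {reason}")


class UndefinedIndexSignal(SegmetalsError):
    """The dissimilarity index is undefined (a group total is zero)."""

    def __init__(self, county_id: str, group: str):
        self.county_id = county_id
        self.group = group
        super().__init__(
            f"county {county_id}: dissimilarity index undefined, "
            f"group {group!r} has zero population"
        )
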