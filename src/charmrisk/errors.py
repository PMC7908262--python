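"""Exception hierarchy for charmrisk.

Numeric domain violations (negative concentration, zero reference
concentration, ...) raise plain :class:`ValueError`; the classes here mark
failures of the assessment workflow itself — bad input files, missing
assessment routes, inconsistent configuration.
"""


class CharmRiskError(Exception):
    """Base class for all charmrisk-specific errors."""


class SchemaError(CharmRiskError):
    """An input table is missing a required column or has the wrong shape."""


class RowError(CharmRiskError):
    """A single data row is invalid (bad CAS, out-of-vocabulary value, ...).

    ``row`` is the 1-based data-row number within the offending file.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class InsufficientDataError(CharmRiskError):
    """No assessment route is available for the requested operation."""


class NoHazardRouteError(InsufficientDataError):
    """Substance has no CMR classification, no OEL and no H-phrases."""


class NoOELError(InsufficientDataError):
    """An OEL-based ratio was requested for a substance without an OEL."""


class ConfigError(CharmRiskError):
    """Run configuration is inconsistent (non-increasing band edges, ...)."""
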