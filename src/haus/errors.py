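"""Exception hierarchy shared across the package."""


class HausError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HausError):
    """An input file does not conform to its documented column schema."""


class ValidationError(HausError):
    """A record violates a domain invariant (e.g. non-positive odds ratio)."""


class ConfigurationError(HausError):
    """A scenario or config references something that is not available."""


class MissingRateError(HausError):
    """No rate row covers a requested (outcome, age band, kind) lookup."""


class EvaluationError(HausError):
    """An evaluation was attempted on degenerate input (e.g. empty population)."""


class ValuationError(HausError):
    """A requested monetization basis is not populated for an outcome."""


class AggregationError(HausError):
    """Report rows cannot be aggregated (e.g. duplicate keys in one scenario)."""
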