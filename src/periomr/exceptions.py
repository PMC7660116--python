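"""Exception hierarchy used across the pipeline."""


class PeriomrError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PeriomrError):
    """A user-supplied configuration (column map, run config) is invalid."""


class ValidationError(PeriomrError):
    """Input records violate a data invariant (bad allele, non-positive se, ...)."""


class HarmonizationError(PeriomrError):
    """Exposure and outcome datasets cannot be reconciled (e.g. no overlap)."""
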