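"""Exception types raised across the pipeline."""


class MRMediateError(Exception):
    """Base class for package errors."""


class SumStatsFormatError(MRMediateError):
    """A summary-statistics file is malformed (e.g. a mandatory column is missing)."""


class DuplicateVariantError(SumStatsFormatError):
    """Duplicate variant identifiers in one summary-statistics table."""

    def __init__(self, duplicates):
        self.duplicates = list(duplicates)
        shown = ", ".join(self.duplicates[:10])
        more = "" if len(self.duplicates) <= 10 else f" (+{len(self.duplicates) - 10} more)"
        super().__init__(f"duplicate variant_id values: {shown}{more}")


class MissingEAFError(MRMediateError):
    """An operation needing the effect-allele frequency met a record without one."""


class InsufficientInstrumentsError(MRMediateError):
    """Fewer instruments than an estimator's minimum."""


class DegenerateInstrumentError(MRMediateError):
    """An instrument with zero exposure effect cannot form a Wald ratio."""


class MediationError(MRMediateError):
    """Undefined mediation quantity (e.g. zero total effect)."""


class ConfigError(MRMediateError):
    """Invalid configuration value; the message names the field."""
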