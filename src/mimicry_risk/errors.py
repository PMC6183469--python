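"""Exception hierarchy for mimicry_risk."""


class MimicryRiskError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MimicryRiskError):
    """A required column is missing or a value does not parse."""


class ReferentialError(MimicryRiskError):
    """A trial references a respondent that does not exist."""


class ConsistencyError(MimicryRiskError):
    """A picture identifier maps to more than one true species."""


class ValidationError(MimicryRiskError):
    """A dataset violates one or more structural invariants."""


class EmptyInputError(MimicryRiskError):
    """An operation received an empty dataset or zero trials."""


class ConfigError(MimicryRiskError):
    """A generator or analysis configuration field is invalid."""


class EstimabilityError(MimicryRiskError):
    """A fixed-factor level has no observations after subsetting."""


class BoundaryError(MimicryRiskError):
    """An estimate sits on the parameter-space boundary (k = 0 or k = n)."""


class PipelineError(MimicryRiskError):
    """The end-to-end analysis cannot proceed (e.g. no selective killers)."""
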