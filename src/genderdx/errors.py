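"""Exception hierarchy for genderdx."""


class GenderdxError(Exception):
    """Base class for all genderdx errors."""


class InvalidConfigError(GenderdxError):
    """A simulation or pipeline configuration violates its invariants."""


class EmptyInputError(GenderdxError):
    """An operation received an empty cohort or matrix."""


class DegenerateCodeError(GenderdxError):
    """A diagnostic code has a degenerate (0 or 1) prevalence or a zero
    cell in its sex cross-table, so its odds ratio is undefined."""


class FitFailureError(GenderdxError):
    """A likelihood maximization failed to converge."""


class MissingRateError(GenderdxError):
    """A (sex, age, year) key could not be resolved in the life table."""


class SchemaError(GenderdxError):
    """An input file does not conform to the expected schema."""


class ReferenceMissingError(GenderdxError):
    """The reference outcome category ("home") is absent from the data."""


class InvalidComparisonError(GenderdxError):
    """A model comparison was requested between non-nested or
    unequal-complexity models where the method does not apply."""
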