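"""Exception hierarchy shared across the package."""


class BapRiskError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BapRiskError):
    """An input table is missing a required column or has an unusable layout."""


class EmptyInputError(BapRiskError):
    """An operation that requires data received none."""


class IntegrityError(BapRiskError):
    """Referential integrity between linked tables is broken."""


class InsufficientDataError(BapRiskError):
    """Too few observations for the requested statistical procedure."""


class ParameterError(BapRiskError):
    """A parameter is out of its valid range or of the wrong kind."""


class InfeasibleMomentsError(ParameterError):
    """Summary statistics are incompatible with the requested distribution family."""
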