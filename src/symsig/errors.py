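"""Package-wide exception types, mapped to CLI exit codes."""


class SymsigError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigurationError(SymsigError):
    """Invalid configuration: impossible schedule, unknown tag, bad parameter."""

    exit_code = 2


class DataIntegrityError(SymsigError):
    """Inputs violate a structural contract (duplicates, missing covariates)."""

    exit_code = 1


class NumericalError(SymsigError):
    """A model fit failed beyond every fallback."""

    exit_code = 3
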