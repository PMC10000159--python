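"""Exception hierarchy shared across the package."""


class EthochainError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EthochainError):
    """A structured-text config failed to parse or is internally invalid."""


class ValidationError(EthochainError):
    """Input violates a declared invariant (duplicate code, bad probability...)."""


class FormatError(EthochainError):
    """A data file is structurally malformed (e.g. missing column)."""


class ScoringError(EthochainError):
    """Questionnaire scoring could not be completed (e.g. missing item)."""


class ConvergenceError(EthochainError):
    """Iterative steady-state computation failed to converge."""
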