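"""Exception hierarchy used across the package."""


class OugazeError(Exception):
    """Base class for all package errors."""


class SchemaError(OugazeError, KeyError):
    """A required column is missing from a tabular input."""


class ValidationError(OugazeError, ValueError):
    """An input violates a documented invariant."""


class ContractError(OugazeError, ValueError):
    """A precondition of an operation was violated."""


class ConfigError(OugazeError, ValueError):
    """A configuration value is out of its admissible range."""


class DependencyError(OugazeError, FileNotFoundError):
    """A pipeline stage is missing an upstream artefact."""


class StratificationError(ValidationError):
    """A subject has too few scan paths for the requested CV fold count."""
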