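"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, ValidationError -> 3,
NumericalError -> 4.
"""


class CopulanetError(Exception):
    """Base class for all package errors."""


class ConfigError(CopulanetError):
    """Invalid configuration value or combination."""


class ValidationError(CopulanetError):
    """Input data violates the variable dictionary contract."""


class NumericalError(CopulanetError):
    """A numerical routine failed (e.g. positive-definiteness lost)."""
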