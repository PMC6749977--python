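"""Exception hierarchy; the CLI maps these onto exit codes."""


class RiboshiftError(Exception):
    """Base class for all package errors."""


class InputError(RiboshiftError):
    """Malformed or inconsistent user input (CLI exit code 2)."""


class ConfigError(InputError):
    """Invalid configuration value."""


class NumericalError(RiboshiftError):
    """Numerical failure during model fitting (CLI exit code 3)."""
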