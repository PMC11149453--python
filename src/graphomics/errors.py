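"""Exception hierarchy shared across the package.

The CLI maps each class to a distinct exit code, so library code should
raise the most specific one that applies.
"""


class GraphomicsError(Exception):
    """Base class for all package errors."""


class InputError(GraphomicsError, ValueError):
    """Invalid argument, configuration value, or inconsistent inputs."""


class ParseError(GraphomicsError, ValueError):
    """Malformed on-disk input (wrong column count, bad value, ...)."""


class NumericError(GraphomicsError, ArithmeticError):
    """Non-finite values encountered during optimization or scoring."""
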