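"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, NumericalError -> 3,
ConvergenceError -> 4.
"""


class DMFitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DMFitError):
    """Invalid or inconsistent configuration / input files."""


class NumericalError(DMFitError):
    """Numerical failure during integration (NaN / blow-up)."""


class ConvergenceError(DMFitError):
    """An iterative procedure failed to converge."""
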