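"""Exception hierarchy shared across the package.

Input problems (bad sequences, malformed tables, out-of-bounds coordinates)
raise :class:`InputError`; bad simulation/configuration values raise
:class:`ConfigError` naming the offending field; fit failures raise
:class:`FitConvergenceError` carrying per-start diagnostics. The CLI maps
these to exit codes 2 (input/config) and 3 (convergence).
"""


class BacpanError(Exception):
    """Base class for all package errors."""


class InputError(BacpanError):
    """Malformed or inconsistent user input."""


class ConfigError(BacpanError):
    """Invalid simulation or analysis configuration."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class ConsistencyError(BacpanError):
    """Internal cross-references disagree (e.g. family table vs proteomes)."""


class FitConvergenceError(BacpanError):
    """Nonlinear fit failed to converge from every starting point."""

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics or []
        super().__init__(message)
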