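"""Exception hierarchy.

Each branch maps to a distinct CLI exit code (see :mod:`iodose.cli`):
validation problems (bad user input), convergence failures (the optimiser),
data-integrity problems (shipped or user-supplied data files), and
configuration errors (unsupported model/route combinations).
"""


class IodoseError(Exception):
    """Base class for all package errors."""


class ValidationError(IodoseError):
    """User-supplied values violate a documented precondition."""


class UnknownNuclideError(IodoseError, LookupError):
    """Requested symbol is not in the nuclide registry."""

    def __init__(self, symbol: str, available: list[str]):
        self.symbol = symbol
        self.available = sorted(available)
        super().__init__(
            f"unknown nuclide {symbol!r}; registry contains: {', '.join(self.available)}"
        )


class DataIntegrityError(IodoseError):
    """A shipped or user-supplied data file is internally inconsistent."""


class ConfigurationError(IodoseError):
    """Requested route/model/table combination is not available."""


class UnsupportedModelError(ConfigurationError):
    """No coefficient data shipped for the requested model variant."""


class FitFailureError(IodoseError):
    """All optimiser starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
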