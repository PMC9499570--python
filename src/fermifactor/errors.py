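"""Exception hierarchy.

Exit-code mapping used by the CLI: validation errors -> 2, infeasible
configuration -> 3, numerical failures -> 4.
"""


class FermifactorError(Exception):
    """Base class for all package errors."""


class FormatError(FermifactorError):
    """Malformed FCIDUMP or other on-disk data."""


class DataError(FermifactorError):
    """Input violates a physical/mathematical invariant (e.g. non-PSD ERI)."""


class ArgumentError(FermifactorError, ValueError):
    """Invalid argument combination or out-of-range scalar."""


class DegenerateGapError(FermifactorError):
    """Zero or negative HOMO-LUMO gap; the MP2 surrogate refuses such inputs."""


class NumericalError(FermifactorError):
    """Non-convergent or NaN-producing optimization."""


class InfeasibleError(FermifactorError):
    """No surface-code configuration in the search grid meets the success target."""

    def __init__(self, message, best_p_fail=None):
        super().__init__(message)
        self.best_p_fail = best_p_fail


class SelectionError(FermifactorError):
    """Rank-selection grid exhausted without meeting the error threshold."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []
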