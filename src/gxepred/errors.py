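"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4; anything else -> 1.
"""


class GxepredError(Exception):
    """Base class for all package errors."""


class ConfigError(GxepredError):
    """Invalid configuration (bad field values, missing requirements)."""


class DataError(GxepredError):
    """Invalid input data (parse failures, violated table invariants)."""


class PedigreeCycleError(DataError):
    """A pedigree contains an individual that is its own ancestor."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(
            "pedigree cycle detected: " + " -> ".join(map(str, self.cycle))
        )


class NumericalError(GxepredError):
    """Numerical failure (singular system, non-PSD kernel beyond tolerance)."""


class KernelNotPSDError(NumericalError):
    def __init__(self, min_eigenvalue):
        self.min_eigenvalue = float(min_eigenvalue)
        super().__init__(
            f"kernel is not positive semi-definite: smallest eigenvalue "
            f"{self.min_eigenvalue:.3e} below tolerance"
        )
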