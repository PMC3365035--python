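"""Exception types shared across the package."""


class PhyloerosionError(Exception):
    """Base class for package-specific errors."""


class SimulationError(PhyloerosionError):
    """Raised when the ecology simulator reaches an invalid state."""


class CullError(SimulationError):
    """Raised when a pulse cull cannot be applied (too few viable organisms)."""


class DegenerateTreeError(PhyloerosionError, ValueError):
    """Raised when fewer than two genotypes are extant at the sampling time."""


class NonUltrametricError(PhyloerosionError, ValueError):
    """Raised when an input tree's tips are not equidistant from the root."""


class UndefinedStatisticError(PhyloerosionError, ValueError):
    """Raised when a tree-shape statistic is undefined for the given tree."""
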