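"""Exception types raised by qpcrmiss."""


class QpcrError(Exception):
    """Base class for all qpcrmiss errors."""


class ValidationError(QpcrError, ValueError):
    """A dataset violates a structural requirement (shape, duplicates,
    or a (gene, sample-type) cell with zero detected replicates)."""


class ParseError(QpcrError, ValueError):
    """An input table could not be parsed; the message names the row."""


class SeparationError(QpcrError, RuntimeError):
    """Unregularized mechanism fit diverged (perfect separation or a
    single response class)."""


class ConvergenceError(QpcrError, RuntimeError):
    """Numerical failure: decreasing observed-data likelihood or a
    quadrature that could not be evaluated."""
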