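"""Exception hierarchy shared across the engine.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError (and
subclasses) -> 3, ConvergenceError -> 4.
"""


class MixscoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MixscoreError):
    """Invalid configuration value or combination."""


class DataError(MixscoreError):
    """Malformed or inconsistent input data."""


class FormatError(DataError):
    """A file does not follow its declared on-disk format."""


class TruncationError(FormatError):
    """A binary payload is shorter/longer than its header implies."""


class DimensionError(DataError):
    """Operands with incompatible shapes."""


class DomainError(DataError):
    """A numeric argument outside its mathematical domain."""


class EmptyBlockError(DataError):
    """No usable variants remain in a genotype block."""


class ConvergenceError(MixscoreError):
    """An iterative procedure failed to converge."""


class NumericalBreakdownError(ConvergenceError):
    """Non-finite values appeared during an iterative solve."""
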