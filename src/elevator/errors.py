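"""Exception hierarchy shared by all analysis stages.

Every error raised on purpose by this package derives from
:class:`ElevatorError`, so callers (and the command-line layer) can separate
domain failures from genuine bugs.
"""


class ElevatorError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ElevatorError):
    """An input file could not be parsed (names the offending file/record)."""


class EmptySelectionError(ElevatorError):
    """A selection (atoms, chains, residues, ions) matched nothing."""


class ValidationError(ElevatorError):
    """A configuration object violated its schema or internal constraints."""


class ConsistencyError(ElevatorError):
    """Multiple inputs that must agree (residue sets, frames) do not."""


class DegenerateGeometryError(ElevatorError):
    """Geometry too degenerate for the requested operation (e.g. collinear
    fit atoms, zero-length transition vector)."""


class InsufficientDataError(ElevatorError):
    """Not enough observations for the requested statistic."""


class FrameMismatchError(ElevatorError):
    """Coordinates are not expressed in the reference frame of the basis."""


class ConnectivityError(ElevatorError):
    """An elastic network is disconnected (or otherwise has extra zero
    modes)."""


class FitError(ElevatorError):
    """A nonlinear fit failed to converge or the data are degenerate."""
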