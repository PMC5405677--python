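"""Exception hierarchy.

Unit convention used throughout the package: pressure mmHg, flow ml/s,
volume ml, time s, resistance mmHg*s/ml, compliance ml/mmHg,
inertance mmHg*s^2/ml.
"""


class ShuntloopError(Exception):
    """Base class for all package errors."""


class ValidationError(ShuntloopError):
    """A component or netlist violates a structural invariant."""


class ConfigurationError(ShuntloopError):
    """A configuration file or parameter table is incomplete or malformed."""


class DataError(ShuntloopError):
    """An input waveform or derived quantity is physically inadmissible."""


class SolverError(ShuntloopError):
    """The time integrator failed (singular system, divergence, no convergence)."""


class FittingError(ShuntloopError):
    """A least-squares fit failed to converge."""


class AlignmentError(DataError):
    """No usable landmark could be detected for waveform alignment."""
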