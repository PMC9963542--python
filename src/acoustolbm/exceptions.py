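"""Exception hierarchy shared across the simulator.

Every failure mode maps onto one of these so that the command-line layer can
translate them into distinct exit codes (configuration / stability /
convergence).
"""


class AcoustoLBMError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AcoustoLBMError, ValueError):
    """A scalar input violates its precondition (names the offending field)."""


class ConfigurationError(AcoustoLBMError):
    """A run configuration is inconsistent or incomplete."""


class StabilityError(AcoustoLBMError):
    """The lattice solution became non-physical (NaN or non-positive density)."""


class ConvergenceError(AcoustoLBMError):
    """A steady-state run exhausted its step budget without converging."""


class OutOfDomainError(AcoustoLBMError):
    """A Lagrangian membrane node left the valid interior of the lattice."""


class WallContactError(AcoustoLBMError):
    """The particle membrane touched a channel wall during a focusing run."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory
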