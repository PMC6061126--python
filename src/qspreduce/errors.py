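"""Exception hierarchy for qspreduce."""


class QSPReduceError(Exception):
    """Base class for all qspreduce errors."""


class ConfigurationError(QSPReduceError):
    """Inconsistent or invalid user configuration (bad channel, empty output set...)."""


class IntegrationError(QSPReduceError):
    """ODE solver failed to converge.

    Attributes
    ----------
    time : float or None
        Time at which integration failed, when known.
    """

    def __init__(self, message, time=None):
        super().__init__(message)
        self.time = time


class StabilityError(QSPReduceError):
    """An operation requiring a Hurwitz system was given an unstable one."""

    def __init__(self, message, eigenvalues=None):
        super().__init__(message)
        self.eigenvalues = eigenvalues


class ValidationError(QSPReduceError):
    """A structural invariant of a model or operator is violated."""


class WiringError(QSPReduceError):
    """Model linkage refers to channels that do not exist or do not match."""


class UndefinedErrorMetric(QSPReduceError):
    """Relative error is undefined (reference output identically zero)."""


class UnsupportedSBMLFeature(QSPReduceError):
    """SBML document uses constructs outside the supported subset."""

    def __init__(self, message, features=()):
        super().__init__(message)
        self.features = list(features)
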