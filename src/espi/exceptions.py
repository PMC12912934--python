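"""Typed errors raised by the plasticity-index machinery.

Degenerate data (zero variance, coincident environments) raise dedicated
exception types so that batch drivers can log and skip individual
trait x day cells instead of aborting a whole run.
"""


class EspiError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EspiError, ValueError):
    """Input violates a precondition (too few replicates, bad config, ...)."""


class DegenerateVarianceError(EspiError):
    """Both groups have zero pooled variance; a standardized effect is undefined."""


class ZeroDistanceError(EspiError):
    """Selected conditions share environmental coordinates; *ESPI is undefined.

    Carries the offending condition pair in ``args`` when raised by the
    pipeline.
    """


class FitConvergenceError(EspiError):
    """Nonlinear least squares did not converge; carries initial values."""

    def __init__(self, message, p0=None):
        super().__init__(message)
        self.p0 = p0
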