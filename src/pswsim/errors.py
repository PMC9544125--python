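"""Exception hierarchy for simulation and estimation failures.

Replicate-level failures (separation, empty groups, degenerate resamples)
are caught by the engine and recorded rather than aborting a run.
"""


class PswsimError(Exception):
    """Base class for all package errors."""


class CalibrationError(PswsimError):
    """Bisection failed to bracket or converge on a calibration target."""


class FitFailureError(PswsimError):
    """Propensity model could not be fit (separation / non-convergence)."""


class EstimateUndefinedError(PswsimError):
    """A point estimate or variance is undefined on this sample
    (empty weighted group, zero event proportion for a log relative risk,
    singular bread matrix, ...)."""


class TrimmingError(PswsimError):
    """Trimming produced an unusable sample (e.g. one treatment arm empty)."""
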