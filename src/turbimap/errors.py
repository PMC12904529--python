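"""Exception hierarchy.

``ValidationError`` covers malformed inputs and configuration (CLI exit
code 2); ``DegenerateDataError`` covers inputs that are structurally fine
but carry too little information for the requested estimate (CLI exit
code 3).
"""


class TurbimapError(Exception):
    """Base class for all package errors."""


class ValidationError(TurbimapError, ValueError):
    """Invalid parameter, geometry, or file content."""


class AngularCoverageError(ValidationError):
    """The camera view sectors leave part of the circumference unobserved."""

    def __init__(self, gaps_rad):
        self.gaps_rad = list(gaps_rad)
        pretty = ", ".join(f"[{lo:.4f}, {hi:.4f}] rad" for lo, hi in self.gaps_rad)
        super().__init__(f"view sectors leave uncovered angular gap(s): {pretty}")


class DegenerateDataError(TurbimapError, ValueError):
    """Data too sparse, saturated, or flat to support the estimate."""


class InsufficientSamplesError(DegenerateDataError):
    """Fewer valid samples than the estimator requires."""
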