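"""Exception taxonomy for model specification, fitting and federation failures."""


class FedGamlssError(Exception):
    """Base class for all package errors."""


class SpecificationError(FedGamlssError, ValueError):
    """Invalid model specification (formula, family, control, data schema size)."""


class DomainError(FedGamlssError, ValueError):
    """Response or parameter value outside the distribution's support/domain."""


class NumericalStabilityError(FedGamlssError, ArithmeticError):
    """Non-finite score/weight or otherwise degenerate numerical state."""


class RangeError(FedGamlssError, ValueError):
    """Covariate value outside the knot-supported spline domain."""


class ExtrapolationError(RangeError):
    """Prediction requested outside the fitted smooth's knot domain."""


class RankDeficiencyError(FedGamlssError, ArithmeticError):
    """Penalized least-squares system is singular or ill-conditioned."""


class ConvergenceError(FedGamlssError, ArithmeticError):
    """Fitting iterations diverged beyond recovery (step-halving exhausted)."""


class HarmonizationError(FedGamlssError, ValueError):
    """Node data schemas are inconsistent with each other or with the model."""


class DisclosureError(FedGamlssError, PermissionError):
    """A privacy guard blocked the requested computation."""


class ProtocolError(FedGamlssError, RuntimeError):
    """Malformed or non-conformable federation message."""
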