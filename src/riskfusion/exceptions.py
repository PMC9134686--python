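"""Exception hierarchy for riskfusion."""


class RiskFusionError(Exception):
    """Base class for all riskfusion errors."""


class InvalidScenarioError(RiskFusionError):
    """Scenario configuration cannot support the experimental design."""


class StratificationError(RiskFusionError):
    """Too few events to produce a stratified split or cross-validation folds."""


class UndefinedMetricError(RiskFusionError):
    """Metric is undefined for the given inputs (e.g. single-class labels)."""


class AlignmentError(RiskFusionError):
    """Feature columns or ensemble member keys cannot be aligned."""


class DegenerateWeightsError(RiskFusionError):
    """All fusion-weight numerators vanished; carries a uniform-weight fallback.

    The ``fallback`` attribute holds a mean-scheme WeightVector that callers
    may adopt (the documented fallback) after logging the degeneracy.
    """

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback


class NoEventsError(RiskFusionError):
    """A (sub)sample contains no outcome events (or no non-events)."""


class InvalidDesignError(RiskFusionError):
    """Leave-one-database-out design requirements are not met."""
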