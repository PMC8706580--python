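"""Exception types raised across the pipeline."""


class CompositionError(ValueError):
    """A food composition violates a domain constraint."""


class UnitCompletenessError(CompositionError):
    """A nutrient field is missing and cannot be derived from a counterpart."""


class RatioUndefinedError(CompositionError):
    """Saturated-fat ratio requested for an added fat with zero total fat."""


class UnresolvableItemError(KeyError):
    """A receipt line references an item absent from the same-day offer."""


class UndefinedWeightingError(ValueError):
    """Energy-weighted meal score requested for a meal with zero total energy."""


class InestimableContrastError(ValueError):
    """A site x period cell of the difference-in-differences design is empty."""


class ConvergenceError(RuntimeError):
    """The mixed-model optimiser failed to converge; carries diagnostics."""


class ConfigError(ValueError):
    """A simulation or run configuration violates its invariants."""
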