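"""Exception hierarchy for the two-stage preference-trial toolkit."""


class PreferenceTrialError(ValueError):
    """Base class for all package-specific errors."""


class ValidationError(PreferenceTrialError):
    """Input records or configuration violate the design's constraints."""


class EstimationImpossibleError(PreferenceTrialError):
    """A required observable subgroup is empty or lacks a defined statistic."""


class DegenerateDesignError(PreferenceTrialError):
    """A denominator of the form 2*alpha*beta*m vanishes (nobody chose A or B)."""


class UndefinedContrastError(PreferenceTrialError):
    """A contrast involving the undecided stratum was requested with gamma = 0."""
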