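"""Exception hierarchy shared across tagbias modules."""


class TagbiasError(Exception):
    """Base class for all tagbias errors."""


class FeasibilityError(TagbiasError, ValueError):
    """A requested parameter combination violates a probabilistic bound.

    The message names the violated bound (e.g. a Fréchet bound on a
    haplotype mass, or an exposure prevalence that cannot be attained).
    """


class MonomorphicLocusError(TagbiasError, ValueError):
    """LD statistics are undefined when either locus is monomorphic."""


class UndefinedStratumError(TagbiasError, ValueError):
    """A (marker, exposure) stratum has zero probability mass."""


class LinkDomainError(TagbiasError, ValueError):
    """A linear predictor maps outside the valid mean domain of the link."""


class InfeasibleObservationError(TagbiasError, ValueError):
    """No positive causal risk ratios can reproduce the observed marker
    effects for the assumed causal MAF and LD."""


class NonIdentifiableError(TagbiasError, ValueError):
    """The inversion is under-determined (e.g. both stratum effects are 1,
    so the exposure tilt drops out of the equations)."""


class ConfigError(TagbiasError, ValueError):
    """Invalid simulation or scenario configuration."""


class SamplingBudgetError(TagbiasError, RuntimeError):
    """Rejection sampling failed to reach the requested case/control counts
    within the iteration cap (disease prevalence too low for the budget)."""
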