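"""Exception hierarchy.

Everything raised on purpose derives from :class:`MRKitError`, so callers can
catch one type at a pipeline boundary while tests distinguish the precise
failure mode.
"""


class MRKitError(Exception):
    """Base class for all errors raised by mrkit."""


class ValidationError(MRKitError):
    """An input value violates a documented invariant (bad SE, allele, r2...)."""


class ConfigurationError(MRKitError):
    """A run/option problem: missing column, missing sample size, bad config key."""


class EmptyInputError(MRKitError):
    """An operation received zero usable rows."""


class NoOverlapError(MRKitError):
    """Exposure and outcome tables share no SNP identifiers."""


class UndefinedRatioError(MRKitError):
    """A Wald ratio was requested with a zero SNP-exposure effect."""


class InsufficientInstrumentsError(MRKitError):
    """Fewer instruments than the estimator's minimum (e.g. Egger needs 3)."""


class DegenerateDesignError(MRKitError):
    """The regression design carries no information (all-zero or constant column)."""


class UnderIdentifiedError(MRKitError):
    """MVMR design with J <= K instruments cannot identify the direct effects."""


class CollinearityError(MRKitError):
    """MVMR exposure-effect columns are (numerically) linearly dependent."""


class AllOutliersError(MRKitError):
    """An outlier scan flagged every instrument; refusing to re-estimate on nothing."""
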