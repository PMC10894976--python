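"""Exception hierarchy for mrpath."""


class MRError(Exception):
    """Base class for all mrpath errors."""


class ConfigurationError(MRError):
    """A required column mapping, path, or config entry is missing or invalid."""


class ValidationError(MRError):
    """Input values violate a documented invariant (e.g. p-value outside (0, 1])."""


class EmptyInputError(MRError):
    """No usable rows remain (empty file, empty variant intersection, ...)."""


class InsufficientInstrumentsError(MRError):
    """Fewer instruments than the estimator's minimum.

    IVW needs k >= 2 (use :func:`mrpath.estimators.wald_ratio` for a single
    SNP), Egger and the median/mode estimators need k >= 3, MR-PRESSO k >= 4,
    and MV-IVW needs k > m.
    """


class UndefinedRatioError(MRError):
    """Wald ratio with a zero exposure effect."""


class UndefinedProportionError(MRError):
    """Mediation proportion with a zero total effect."""


class CollinearityError(MRError):
    """Rank-deficient exposure matrix in multivariable MR."""

    def __init__(self, message, exposures=None):
        super().__init__(message)
        self.exposures = list(exposures or [])
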