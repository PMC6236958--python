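"""Exception hierarchy for cscompliance."""


class CSComplianceError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CSComplianceError):
    """A physical circuit parameter is non-positive or non-finite."""


class InvalidConfigError(CSComplianceError):
    """An estimator configuration value is out of its allowed range."""


class UnstableModelError(CSComplianceError):
    """A transfer function has poles on or outside its stability boundary."""


class DegenerateGainError(CSComplianceError):
    """H(z) has a pole at z=1, so the dc gain is undefined."""


class DegenerateInputError(CSComplianceError):
    """The regression design built from the input waveform is rank deficient."""


class UndefinedEError(CSComplianceError):
    """Nash-Sutcliffe efficiency is undefined (constant observed sequence)."""


class NoSolutionError(CSComplianceError):
    """No grid quartet reached the Nash-Sutcliffe acceptance threshold.

    Carries ``best_e``, the largest efficiency observed, so callers can
    decide whether relaxing the threshold is defensible.
    """

    def __init__(self, best_e: float, threshold: float):
        self.best_e = float(best_e)
        self.threshold = float(threshold)
        super().__init__(
            f"no stable quartet reached E > {threshold:g} (best E = {best_e:.4f})"
        )


class WaveformParseError(CSComplianceError):
    """A waveform CSV file could not be parsed into a subject record."""
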