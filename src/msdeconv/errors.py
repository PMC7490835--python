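"""Exception hierarchy for msdeconv.

All errors raised by the package derive from :class:`MsDeconvError` so that
callers (and the CLI) can catch pipeline failures with a single handler.
"""


class MsDeconvError(Exception):
    """Base class for all msdeconv errors."""


class InvalidBasisError(MsDeconvError):
    """A basis spectrum is empty, all-zero, negative, or on a non-integer grid."""


class MixedDetectorError(MsDeconvError):
    """Faraday-cup and electron-multiplier data were mixed in one fit or group."""


class MissingDataError(MsDeconvError):
    """A peak-height group has no PEAK-type readings."""


class UnderdeterminedSystemError(MsDeconvError):
    """Fewer measured peaks than basis spectra (M < N)."""


class CollinearBasisError(MsDeconvError):
    """The design matrix is rank-deficient or numerically singular."""


class UndefinedFractionError(MsDeconvError):
    """No basis spectrum contributes ion current at the requested m/z."""


class BlockParseError(MsDeconvError):
    """A DECONVOLUTION block or readings line could not be parsed."""


class ConfigError(MsDeconvError):
    """Inconsistent configuration (e.g. target species absent from basis)."""


class CalibrationError(MsDeconvError):
    """Sample and reference peaks are incompatible, or the reference is invalid."""


class ModelMismatchWarning(UserWarning):
    """A fitted coefficient is significantly negative, or χ² indicates misfit."""
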