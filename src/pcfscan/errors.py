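"""Exception hierarchy shared across the package."""


class PcfScanError(Exception):
    """Base class for all pcfscan errors."""


class FormatError(PcfScanError):
    """A file on disk is malformed or uses an unsupported encoding."""


class ConfigurationError(PcfScanError):
    """Required configuration (sidecar metadata, simulation config) is
    missing or inconsistent.  Missing fields are never silently defaulted."""


class ValidationError(PcfScanError, ValueError):
    """An in-memory object violates one of its invariants."""


class NormalizationError(PcfScanError):
    """The fluctuation estimator is undefined (zero-mean intensity record)."""


class RatioUndefinedError(PcfScanError):
    """A concentration ratio has a zero denominator."""


class FitError(PcfScanError):
    """Nonlinear fitting failed."""


class FitInfeasibleError(FitError):
    """The curve carries no fittable signal (e.g. nowhere positive)."""


class CalibrationError(PcfScanError):
    """Permeability or PSF calibration failed."""


class InfeasibleTargetError(CalibrationError):
    """The requested calibration target is outside the physically
    reachable range (e.g. shorter than the free-diffusion passage time)."""
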