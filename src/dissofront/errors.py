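"""Exception hierarchy shared across the package."""


class DissofrontError(Exception):
    """Base class for all package-specific errors."""


class TabletNotFoundError(DissofrontError):
    """No usable foreground region in frame 0."""


class AmbiguousForegroundError(DissofrontError):
    """More than one comparable foreground region in frame 0."""


class GeometryMismatchError(DissofrontError):
    """Stack dimensions inconsistent with a previously computed geometry."""


class InsufficientPointsError(DissofrontError):
    """Too few observations for a regression or a fit."""


class BadTimeAxisError(DissofrontError):
    """Time values not strictly increasing (or not starting at 0)."""


class FitFailedError(DissofrontError):
    """Every optimizer start failed to converge."""


class InvalidParametersError(DissofrontError):
    """Model parameters outside their declared bounds."""


class DegenerateDataError(DissofrontError):
    """Observations carry no variance (or predictor is constant)."""


class SceneSpecError(DissofrontError):
    """Synthetic scene specification is inconsistent or unrenderable."""


class ConfigError(DissofrontError):
    """Run configuration failed schema validation."""
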