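"""Exception hierarchy for oncotoc."""


class OncotocError(Exception):
    """Base class for all package-specific errors."""


class ModelError(OncotocError):
    """Invalid random-process model parameters (e.g. non-PSD covariance)."""


class CapacityError(OncotocError):
    """Problem size exceeds what a dense algorithm is allowed to attempt."""


class GridMismatchError(OncotocError):
    """Two fields do not share a grid and/or time sampling."""


class ResolutionError(OncotocError):
    """A discretization (e.g. the characteristic-function grid) is too coarse."""


class CapabilityError(OncotocError):
    """The requested analytic route is not available for this model."""


class ConfigError(OncotocError):
    """An experiment configuration failed validation."""
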