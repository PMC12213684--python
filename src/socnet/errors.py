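"""Structured exceptions raised across the package."""


class SocnetError(ValueError):
    """Base class for all package-specific errors."""


class InfeasibleNetworkError(SocnetError):
    """A network specification cannot be realised (e.g. avg_degree >= N)."""


class InsufficientDataError(SocnetError):
    """An operation received too few observations to be meaningful."""


class DegenerateCatalogError(SocnetError):
    """An avalanche catalog has no spread (all sizes equal) and cannot be fit."""


class WindowError(SocnetError):
    """A requested averaging window is not covered by the available series."""
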