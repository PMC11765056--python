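"""Exception hierarchy shared across the package."""


class DoseCastError(Exception):
    """Base class for all package-specific failures."""


class DomainError(DoseCastError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(DoseCastError, ValueError):
    """An on-disk file is malformed (bad index, non-binary mask, ...)."""


class LoadError(DoseCastError, IOError):
    """A required file is missing or unreadable."""


class GenerationError(DoseCastError, RuntimeError):
    """A synthetic phantom could not be constructed on the requested grid."""


class FitError(DoseCastError, ValueError):
    """A statistic could not be fitted (e.g. zero intensity variance)."""


class ConfigError(DoseCastError, ValueError):
    """A model or training configuration is internally inconsistent."""
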