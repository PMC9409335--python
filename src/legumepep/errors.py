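"""Exception hierarchy shared across the package."""


class LegumepepError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(LegumepepError):
    """An input file or collection was empty where content is required."""


class AlphabetError(LegumepepError):
    """A sequence contains a character outside the accepted amino-acid alphabet."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class RegistryError(LegumepepError):
    """A modification identifier is not present in the registry."""


class ModificationPlacementError(LegumepepError):
    """A modification was placed on a residue it is not allowed to target."""


class DegenerateControlError(LegumepepError):
    """A control/blank signal makes a percent transform undefined."""


class DegenerateTraceError(LegumepepError):
    """A kinetic trace cannot be normalised (zero initial fluorescence)."""


class FitError(LegumepepError):
    """A regression design is singular or otherwise unusable."""


class ConfigError(LegumepepError):
    """A pipeline configuration is invalid."""
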