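"""Structured exceptions shared across the package.

All computational failures raise a subclass of :class:`BioalbedoError`, which
the command-line layer maps to exit code 1 (usage problems exit with 2).
"""


class BioalbedoError(Exception):
    """Base class for all bioalbedo computational errors."""


class SpectrumError(BioalbedoError):
    """Invalid spectrum data (non-monotone grid, out-of-range values...)."""


class GridMismatchError(SpectrumError):
    """Spectra could not be placed on a common wavelength grid."""


class CoverageError(SpectrumError):
    """A requested wavelength window is not covered by the data."""


class PanelError(SpectrumError):
    """Reference-panel radiance unusable (non-positive at some wavelength)."""


class RegressionError(BioalbedoError):
    """Degenerate design for the density-IRF regression."""


class SceneError(BioalbedoError):
    """Malformed multiband scene (missing band, shape mismatch...)."""


class WeatherError(BioalbedoError):
    """Weather series failed validation (irregular cadence, large gaps...)."""


class ParseError(BioalbedoError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}: "
        if line is not None:
            loc += f"line {line}: "
        super().__init__(loc + message)
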