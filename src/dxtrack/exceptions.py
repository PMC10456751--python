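"""Exception hierarchy for dxtrack.

All package errors derive from :class:`DXTError` so callers can catch the
whole family with one clause while the pipeline reports the failing stage.
"""


class DXTError(Exception):
    """Base class for all dxtrack errors."""


class FormatError(DXTError):
    """A file does not conform to the expected tabular layout."""


class DataError(DXTError):
    """Well-formed input whose content violates a data invariant."""


class ConfigError(DXTError):
    """An invalid or internally inconsistent run configuration."""


class GeometryError(DXTError):
    """A detector-geometry operation outside its valid domain."""


class NoDiffractionError(GeometryError):
    """The Bragg condition cannot be satisfied (wavelength exceeds 2d)."""


class FitError(DXTError):
    """A curve fit could not be performed on the given data."""


class EmptyEnsembleError(DXTError):
    """An operation that needs trajectories received none."""
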