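"""Exception and warning hierarchy for kinstab.

Every error raised by the library derives from :class:`KinstabError`;
recoverable conditions are issued through :mod:`warnings` with the
warning categories defined here.
"""


class KinstabError(Exception):
    """Base class for all kinstab errors."""


# -- spectra ---------------------------------------------------------------

class InvalidSignal(KinstabError):
    """Signal values violate a physical precondition (e.g. negative intensity)."""


class DegenerateSpectrum(KinstabError):
    """Spectrum carries no usable signal (e.g. all-zero intensities)."""


class InvalidGeometry(KinstabError):
    """Non-physical cuvette geometry or concentration."""


class GridMismatch(KinstabError):
    """Spectra in a series do not share a common wavelength grid."""


# -- unfolding -------------------------------------------------------------

class InvalidSlope(KinstabError):
    """An m value (dG/d[denaturant] slope) must be strictly positive."""


class UnbracketedTransition(KinstabError):
    """Denaturation series lacks a pre- or post-transition baseline."""


class FitDiverged(KinstabError):
    """Nonlinear least squares failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoModel(KinstabError):
    """Neither candidate unfolding model could be fitted."""


# -- thermal ---------------------------------------------------------------

class InvalidScan(KinstabError):
    """Thermal scan grid is not strictly increasing."""


class NoTransition(KinstabError):
    """No derivative extremum above the prominence threshold."""


# -- kinetics --------------------------------------------------------------

class NoLinearPhase(KinstabError):
    """No candidate early window of a progress curve is acceptably linear."""


class InvalidAssay(KinstabError):
    """Progress curve contradicts the assay model (e.g. negative slope)."""


class InsufficientRange(KinstabError):
    """Too few usable temperature points for an Arrhenius fit."""


class AboveTmaxError(KinstabError):
    """Rate points above the temperature of maximal activity were passed
    to an Arrhenius fit; they must be filtered out explicitly, never
    silently fitted."""


# -- report / io -----------------------------------------------------------

class ParseError(KinstabError):
    """A cell or token failed to parse; message carries row/column."""


class SchemaError(KinstabError):
    """An input table is missing a required column."""


class IncompleteRecord(KinstabError):
    """A variant record lacks the fits required for a comparison."""

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class EmptyReport(KinstabError):
    """Report rendering was asked to format zero rows."""


# -- warnings --------------------------------------------------------------

class KinstabWarning(UserWarning):
    """Base class for kinstab warnings."""


class BoundaryFitWarning(KinstabWarning):
    """A fitted parameter landed on a bound."""


class PoorSaturationWarning(KinstabWarning):
    """Largest substrate concentration below the Km estimate."""


class EdgeMaximumWarning(KinstabWarning):
    """Activity maximum sits at the edge of the temperature grid."""


class TieWarning(KinstabWarning):
    """Two temperatures share the maximal rate; the lower one is reported."""
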