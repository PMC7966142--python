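"""Exception hierarchy for the coilpd pipeline.

Every stage raises a subclass of :class:`CoilPDError` so batch drivers can
attribute failures to a stage and keep going.
"""


class CoilPDError(Exception):
    """Base class for all coilpd errors."""


class SpecError(CoilPDError):
    """Invalid or mutually inconsistent geometry specification."""


class ResolutionError(CoilPDError):
    """Grid spacing too coarse to resolve the requested geometry."""


class GeometryError(CoilPDError):
    """A geometric operation produced an invalid domain."""


class ParameterError(CoilPDError):
    """Invalid physical or statistical parameter values."""


class InstabilityError(CoilPDError):
    """The transient solve blew up; message names the failing step."""


class ToleranceError(CoilPDError):
    """An iterative solve failed to reach its tolerance."""


class PatchError(CoilPDError):
    """A required boundary patch is empty or missing."""


class InputError(CoilPDError):
    """Invalid input data to an analysis routine."""


class DegenerateDataError(InputError):
    """Data degenerate for the requested statistic (e.g. constant sample)."""


class FitError(CoilPDError):
    """Model fit failed to converge; message carries diagnostics."""
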