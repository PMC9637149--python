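"""Exception types raised by the ldics pipeline."""


class LdicsError(Exception):
    """Base class for all ldics-specific failures."""


class SegmentationError(LdicsError):
    """Hypha segmentation produced an empty, full-frame or otherwise unusable mask."""


class FitError(LdicsError):
    """Curve fitting failed to converge or returned non-physical parameters.

    Carries a ``diagnostics`` dict (initial guesses, bounds, data summary)
    to make fit pathologies debuggable.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InfeasibleSpecError(LdicsError):
    """Synthetic-image spec cannot be realized (e.g. droplet density too high
    for the hypha geometry after bounded rejection sampling)."""
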