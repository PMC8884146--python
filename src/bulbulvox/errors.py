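"""Exception hierarchy shared across the pipeline."""


class VoxError(Exception):
    """Base class for all package errors."""


class InvalidConfiguration(VoxError):
    """A configuration violates its invariants (band outside Nyquist, etc.)."""


class CapabilityError(VoxError):
    """A requested backend or optional capability is not available."""


class FeatureError(VoxError):
    """A descriptor or contour could not be computed from the given unit."""


class SynthesisRangeError(VoxError):
    """A frequency contour leaves the synthesizable range (0, Nyquist)."""


class UnderdeterminedFit(FeatureError):
    """Fewer contour points than model coefficients."""


class RepresentationError(VoxError):
    """A unit is too short or malformed for the requested representation."""


class StratificationError(VoxError):
    """A data split would leave one class empty."""


class DegenerateDataError(VoxError):
    """Input data carries no variance to model."""
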