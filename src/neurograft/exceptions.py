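"""Exception hierarchy shared across the package."""


class NeurograftError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeurograftError, ValueError):
    """A simulation or run configuration violates its invariants."""


class InputError(NeurograftError, ValueError):
    """An input array/table violates a precondition (length, channels, labels)."""


class DegenerateBaselineError(InputError):
    """F0 computed as zero; dF/F0 is undefined for this trace."""


class GeometryError(NeurograftError, ValueError):
    """A region or box falls outside the image or misses the boundary."""


class InsufficientDataError(NeurograftError, ValueError):
    """Fewer than two usable (non-degenerate) ROIs for correlation."""


class LabelingError(NeurograftError, KeyError):
    """A non-degenerate ROI is missing a required compartment/layer label."""
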