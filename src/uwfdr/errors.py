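"""Exception hierarchy shared across the pipeline."""


class UwfdrError(Exception):
    """Base class for all package errors."""


class ValidationError(UwfdrError, ValueError):
    """An input violates a documented precondition or invariant."""


class FormatError(UwfdrError, ValueError):
    """An image or mask is not in the expected format (e.g. not 8-bit RGB)."""


class DegenerateGeometryError(UwfdrError, ValueError):
    """Landmark geometry does not define the requested transform/crop."""


class DegenerateMaskError(UwfdrError, ValueError):
    """A segmentation mask is too small for parameter estimation."""


class DegenerateTestError(UwfdrError, ValueError):
    """A statistical test is undefined on this input (e.g. zero variance)."""


class UnsupportedArchitectureError(UwfdrError, TypeError):
    """A model does not expose the structure required by the operation."""
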