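"""Exception types shared across the package."""


class DriftsourceError(Exception):
    """Base class for all package-specific errors."""


class FieldFormatError(DriftsourceError):
    """A gridded-field file is missing a required variable or axis."""


class ValidationError(DriftsourceError, ValueError):
    """An input violates a documented precondition."""


class OutOfRangeError(DriftsourceError, ValueError):
    """A query falls outside the spatial or temporal extent of a field."""


class GeometryError(DriftsourceError):
    """A polygon input is invalid (open or self-intersecting ring)."""
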