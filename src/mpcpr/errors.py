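"""Exception hierarchy shared by all modules."""


class MpcprError(Exception):
    """Base class for all package errors."""


class FormatError(MpcprError):
    """A file exists but does not parse as the named format."""


class UsageError(MpcprError, ValueError):
    """Invalid arguments or degenerate input supplied by the caller."""


class SpecError(MpcprError, ValueError):
    """A phantom specification violates its invariants."""


class TrackingError(MpcprError):
    """Centerline tracking failed (e.g. an unreachable gap)."""


class RenderError(MpcprError):
    """A reformation could not be produced from the given geometry."""


class MappingError(MpcprError):
    """The segment model cannot be mapped onto the tracked tree."""


class DataError(MpcprError, ValueError):
    """Malformed rating / reference tables."""
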