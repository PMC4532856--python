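"""Exception hierarchy shared across the analysis stages."""


class GcgrflexError(Exception):
    """Base class for all package errors."""


class ParseError(GcgrflexError):
    """A structure or table file could not be parsed; names the offending line."""


class StructuralError(GcgrflexError):
    """Topology inconsistency, e.g. atom-count mismatch between trajectory models."""


class EmptySelectionError(GcgrflexError):
    """An atom selection matched nothing (never returned silently)."""


class ValidationError(GcgrflexError):
    """A value violates a documented invariant (e.g. percent outside [0, 100])."""


class DegenerateFrameError(GcgrflexError):
    """The reference frame is undefined (7TM COM on the z axis)."""


class ConfigurationError(GcgrflexError):
    """Inconsistent or missing configuration (e.g. lipids present, no slab)."""


class DisconnectedNetworkError(GcgrflexError):
    """Elastic network splits into several components at the chosen cutoff."""
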