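"""Exception hierarchy."""


class GeocovError(Exception):
    """Base class for all geocov errors."""


class SchemaError(GeocovError):
    """A required attribute/column is missing or malformed."""


class LayerValidationError(GeocovError):
    """A feature violates a layer invariant (e.g. zero-area polygon)."""


class CrsError(GeocovError):
    """Input declares a geographic (degree-based) CRS; reproject first."""


class ConfigurationError(GeocovError):
    """A lookup table or catalog config does not cover the requested case."""


class JoinError(GeocovError):
    """Tabular join failed (duplicate keys or zero matches)."""
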