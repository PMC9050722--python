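"""Exception hierarchy for the tissuerep pipeline.

Every error raised on malformed input derives from :class:`TissuerepError`
so callers (and the CLI) can catch pipeline failures in one place.
"""


class TissuerepError(Exception):
    """Base class for all tissuerep errors."""


class GctFormatError(TissuerepError, ValueError):
    """Malformed GCT file (bad version line, bad dims line, non-numeric cell)."""


class DimensionError(GctFormatError):
    """Declared GCT dimensions disagree with the parsed table."""


class SchemaError(TissuerepError, ValueError):
    """A required column is missing from a tabular input."""


class AnnotationError(TissuerepError, ValueError):
    """Inconsistent transcript annotation (duplicate ids, CDS without exon, ...)."""


class ConfigurationError(TissuerepError, ValueError):
    """Invalid analysis or simulation configuration."""
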