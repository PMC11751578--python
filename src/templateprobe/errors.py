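"""Exception hierarchy shared across the toolkit."""


class TemplateProbeError(Exception):
    """Base class for all toolkit errors."""


class StructureParseError(TemplateProbeError):
    """A structure file could not be parsed."""


class EmptyStructureError(TemplateProbeError):
    """No protein residues remained after filtering."""


class FormatCapacityError(TemplateProbeError):
    """A value does not fit the fixed-width fields of the requested format."""


class ParameterError(TemplateProbeError):
    """An operation was called with invalid parameters."""


class GenerationError(TemplateProbeError):
    """The synthetic-structure generator failed within its retry budget."""


class PairingError(TemplateProbeError):
    """Point or atom sets could not be paired (length mismatch, too few points)."""


class DegenerateGeometryError(TemplateProbeError):
    """Input geometry is degenerate (collinear or coincident points)."""


class MetricUndefinedError(TemplateProbeError):
    """A metric has no defined value for the given inputs (empty pairing)."""


class AlignmentError(TemplateProbeError):
    """Sequence alignment could not be performed."""
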