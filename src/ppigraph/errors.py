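"""Exception hierarchy shared across the package."""


class PPIGraphError(Exception):
    """Base class for all package errors."""


class StructuralInputError(PPIGraphError):
    """A structure file has no usable ATOM content or is otherwise unusable."""


class PDBParseError(PPIGraphError):
    """A PDB record could not be parsed; the message names the offending line."""


class PDBFormatError(PPIGraphError):
    """A structure cannot be serialized into fixed-column PDB records."""


class EncodingError(PPIGraphError):
    """A sequence character falls outside the supported amino-acid alphabet."""


class AlignmentError(PPIGraphError):
    """Feature matrix length does not match the contact-graph node count."""


class EmbeddingLookupError(PPIGraphError, KeyError):
    """Requested protein id is absent from the embedding store."""


class EmbeddingFormatError(PPIGraphError):
    """Stored embedding payload is not a finite 2-D real matrix."""


class ShapeError(PPIGraphError):
    """Array shapes are inconsistent with the layer/model contract."""


class GraphInputError(PPIGraphError):
    """Adjacency matrix violates the symmetric zero-diagonal binary contract."""


class DataError(PPIGraphError):
    """Pair dataset references protein ids with no graph/features available."""


class MetricError(PPIGraphError):
    """A metric is undefined for the given inputs (e.g. single-class labels)."""


class ConfigurationError(PPIGraphError):
    """A run/synthetic configuration is internally inconsistent."""


class GenerationError(PPIGraphError):
    """Synthetic structure generation exhausted its retry budget."""
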