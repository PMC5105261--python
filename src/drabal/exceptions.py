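"""Exception hierarchy shared across the package."""


class DrabalError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(DrabalError):
    """A delimited input file does not have the required columns/shape."""


class DataError(DrabalError):
    """Input data violates an integrity constraint (e.g. conflicting outcomes)."""


class EmptyDatasetError(DrabalError):
    """No compounds survived merging/filtering."""


class ParameterError(DrabalError, ValueError):
    """An argument is outside its documented domain."""


class InsufficientDataError(DrabalError):
    """Too few effective rows to run a conditional-independence test."""


class StructureError(DrabalError):
    """Graph-structure violation (e.g. a cycle where a DAG is required)."""


class DegenerateLabelError(DrabalError):
    """An assay's observed training labels contain a single class."""

    def __init__(self, assay_id: str, message: str | None = None):
        self.assay_id = assay_id
        super().__init__(message or f"assay {assay_id!r} has single-class observed labels")
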