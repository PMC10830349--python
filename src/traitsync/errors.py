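"""Exception hierarchy shared across the pipeline stages."""


class TraitSyncError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(TraitSyncError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(TraitSyncError, ValueError):
    """An input file or text does not conform to the expected format."""


class PipelineError(TraitSyncError, RuntimeError):
    """A pipeline stage cannot proceed (e.g. insufficient pairwise overlap)."""


class DegenerateMatrixError(TraitSyncError, ValueError):
    """A distance matrix has zero variance over its usable entries."""


class CollinearMatricesError(TraitSyncError, ValueError):
    """Two of the matrices in a partial test are perfectly correlated."""


class AlignmentError(TraitSyncError, ValueError):
    """Species label sets cannot be reconciled across inputs."""
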