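"""Exception types shared across the package."""


class FCTransferError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(FCTransferError, ValueError):
    """Array dimensions are inconsistent with the model or operation."""


class InvalidInputError(FCTransferError, ValueError):
    """Inputs violate a precondition (non-finite, empty, wrong domain)."""


class OptimizationError(FCTransferError, RuntimeError):
    """The optimizer encountered non-finite values mid-run."""


class ProvenanceError(FCTransferError, ValueError):
    """A model with the wrong provenance tag was wired into the pipeline."""


class StageError(FCTransferError, RuntimeError):
    """A multi-stage procedure failed; the message names the stage."""
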