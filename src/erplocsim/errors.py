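"""Exception hierarchy for the simulation pipeline."""


class ErpLocSimError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ErpLocSimError, ValueError):
    """A precondition on an argument was violated."""


class ResourceLimitError(ErpLocSimError):
    """A requested computation would exceed a configured size cap."""


class EmptyROIError(ErpLocSimError):
    """An ROI selected no dipoles; the simulation cannot proceed."""


class ProvenanceError(ErpLocSimError):
    """Objects from incompatible models/montages/grids were combined."""


class RankDeficiencyError(ErpLocSimError):
    """A covariance estimate is rank deficient and needs diagonal loading."""


class NumericalError(ErpLocSimError):
    """An iterative numerical procedure failed to converge."""
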