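"""Exception types shared across the package."""


class ColonyStateError(Exception):
    """Base class for package errors."""


class NestConfigError(ColonyStateError, ValueError):
    """Invalid nest geometry configuration (overlap, disconnection, bad opening)."""


class OutsideRegionError(ColonyStateError, ValueError):
    """A point that must lie inside the walkable region does not."""


class AlignmentError(ColonyStateError, ValueError):
    """Camera-clock alignment produced an inconsistent global timeline."""


class FitError(ColonyStateError, RuntimeError):
    """A model fit could not be computed (separation, singularity, no events)."""
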