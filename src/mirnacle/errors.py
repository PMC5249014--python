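"""Exception hierarchy for the mirnacle toolkit."""


class MirnacleError(Exception):
    """Base class for all toolkit errors."""


class InvalidAlphabetError(MirnacleError, ValueError):
    """Sequence contains characters outside {A, C, G, U} after normalization."""


class InvalidInputError(MirnacleError, ValueError):
    """Structurally invalid input (empty sequence, negative count, ...)."""


class InconsistentInputError(MirnacleError, ValueError):
    """Two inputs that must refer to the same object do not."""


class InsufficientLengthError(MirnacleError, ValueError):
    """Sequence too short for the requested profile."""


class EnergyBackendError(MirnacleError, RuntimeError):
    """The energy backend failed; the original cause is chained."""


class TrainingDataError(MirnacleError, ValueError):
    """A training set is unusable (e.g. a class ended up empty)."""


class InsufficientMinorityError(MirnacleError, ValueError):
    """SMOTE needs at least two minority examples."""


class CVConfigurationError(MirnacleError, ValueError):
    """Cross-validation configuration incompatible with the data."""


class InvalidSpecError(MirnacleError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class PlacementError(MirnacleError, ValueError):
    """Hairpins cannot be placed in the requested genome length."""
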