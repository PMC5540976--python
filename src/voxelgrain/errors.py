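"""Exception hierarchy shared across the package."""


class VoxelgrainError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(VoxelgrainError, ValueError):
    """A parameter violates a documented invariant."""


class OutOfDomainError(VoxelgrainError, ValueError):
    """A visual-field location falls outside the stimulus annulus."""


class UnsupportedGeometryError(VoxelgrainError, ValueError):
    """A patch geometry for which a requested labeling is undefined."""


class InvalidDesignError(VoxelgrainError, ValueError):
    """A block design that cannot be realized (overlap, misaligned TR, ...)."""


class SingularDesignError(VoxelgrainError, ValueError):
    """Rank-deficient design matrix supplied to the GLM."""


class DegenerateDataError(VoxelgrainError, ValueError):
    """Data with no usable variance (zero residuals, all-zero differences)."""


class UndefinedIndexError(VoxelgrainError, ValueError):
    """Replicability index requested for a zero-norm vector."""


class InvalidFoldError(VoxelgrainError, ValueError):
    """A cross-validation fold with no usable training data."""


class ConfigurationError(VoxelgrainError, ValueError):
    """An invalid or incomplete pipeline configuration."""
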