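"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: ConfigError -> 2, DataError/FormatError -> 3,
everything else (compute failures) -> 4.
"""


class CESTError(Exception):
    """Base class for all cestpipe errors."""


class GridError(CESTError):
    """Offset-grid definition problem (non-uniform span, duplicates, ...)."""


class ModelError(CESTError):
    """Invalid forward-model specification (e.g. pool amplitudes sum >= 1)."""


class FormatError(CESTError):
    """On-disk data does not match its declared structure."""


class DataError(CESTError):
    """Data values violate a precondition (empty mask, non-finite z, ...)."""


class ConfigError(CESTError):
    """Bad or unknown configuration keys/values."""


class FitError(CESTError):
    """Per-voxel fitting cannot proceed (e.g. too few points for the order)."""


class StatsError(CESTError):
    """Group-comparison preconditions violated."""
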