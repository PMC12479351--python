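"""Exception hierarchy for the land-allocation pipeline.

Every stage raises a subclass of :class:`TripleLandError` so the pipeline
driver can attach stage context and map failures to exit codes
(config errors -> 2, data errors -> 3).
"""


class TripleLandError(Exception):
    """Base class for all package errors."""


class ConfigError(TripleLandError):
    """Invalid configuration (shares not summing to 1, bad step, bad budget...)."""


class DimensionError(ConfigError):
    """Non-positive or inconsistent grid dimensions."""


class DataError(TripleLandError):
    """Invalid data encountered at run time (non-finite inputs, missing surfaces)."""


class AlignmentError(DataError):
    """Grids that must share a shape/transform do not."""


class AssignmentError(DataError):
    """Nearest-neighbour habitat assignment has no donor habitat."""


class SmoothingError(DataError):
    """Outlier smoothing cannot proceed (no valid neighbours anywhere)."""


class DegenerateBoundsError(DataError):
    """Performance normalisation bounds collapse (max == min)."""
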