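"""Exception hierarchy.

Configuration problems (bad parameters, unknown presets) and data problems
(out-of-bounds ROIs, unreadable stacks) are distinguished so the command-line
layer can map them to distinct exit codes.
"""


class KinquantError(Exception):
    """Base class for all package errors."""


class ConfigError(KinquantError):
    """Invalid configuration: bad parameter values, unknown scenario names."""


class DataError(KinquantError):
    """Invalid data: ROIs crossing boundaries, degenerate populations."""


class RoiOutOfBoundsError(DataError):
    """An ROI (kinetochore box, background shell, or fit patch) would cross a
    grid boundary for the named focus."""


class DegenerateReferenceError(DataError):
    """Reference population is empty or has zero mean; normalization undefined."""


class FitFailedError(DataError):
    """A 1D Gaussian fit did not converge or pinned a bounded parameter."""
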