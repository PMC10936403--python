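"""Exception hierarchy shared by all pipeline stages."""


class FtssError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FtssError):
    """Input file does not conform to the expected dialect (missing columns, bad header)."""


class DataError(FtssError):
    """Input data are structurally invalid (non-monotone time, too short, irregular rate)."""


class ParameterError(FtssError):
    """Invalid parameter object (singular calibration matrix, out-of-range fraction)."""


class SegmentationError(FtssError):
    """No sit-to-stand transitions could be detected, or validity gating refused the trial."""


class ContractError(FtssError):
    """An operation was called on an input that violates its contract (e.g. sway features on a thigh recording)."""


class DegenerateInputError(FtssError):
    """Mathematically degenerate input (constant signal, zero mean in a denominator)."""


class ConfigError(FtssError):
    """Invalid run configuration."""
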