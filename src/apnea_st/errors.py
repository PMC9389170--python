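"""Exception types shared across the package."""


class ApneaSTError(Exception):
    """Base class for package errors."""


class FormatError(ApneaSTError):
    """A file does not conform to its expected on-disk format."""


class ConfigError(ApneaSTError):
    """An invalid parameter or layer configuration."""


class ShapeError(ApneaSTError):
    """Array shapes are inconsistent with an operation's contract."""


class SparseBeatsError(ApneaSTError):
    """A 5-min window holds too few beats for cubic interpolation.

    Raised by :func:`apnea_st.preprocessing.resample_window`; callers building
    window sets catch it and drop the segment.
    """
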