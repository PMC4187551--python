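"""Exception hierarchy.

Every rejection the pipeline can produce derives from :class:`LungAdcError`
so callers can distinguish pipeline failures from programming errors.
"""


class LungAdcError(Exception):
    """Base class for all pipeline rejections."""


class VolumeError(LungAdcError):
    """Invalid image volume (dimensionality, spacing, shape mismatch)."""


class ConfigError(LungAdcError):
    """Invalid or unknown configuration keys/values."""


class PhantomError(LungAdcError):
    """Invalid phantom specification or unrealisable geometry."""


class SegmentationError(LungAdcError):
    """Degenerate input image or empty mask after cleanup."""


class AdcError(LungAdcError):
    """ADC mapping rejection (zero b-value, empty validity mask)."""


class RegionalError(LungAdcError):
    """Too few usable slices/rows for a regional statistic."""


class SnrError(LungAdcError):
    """No valid ROI placements or zero noise estimate."""


class CtError(LungAdcError):
    """Empty lung mask or invalid percentile for CT densitometry."""


class StatsError(LungAdcError):
    """Invalid input to a statistical routine."""
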