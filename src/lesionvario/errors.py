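"""Package-wide exception and warning types."""


class MaskFormatError(ValueError):
    """A mask file or array violates the grid/format contract."""


class NonBinaryMaskError(MaskFormatError):
    """A mask contains values other than 0 and 1."""


class ManifestError(ValueError):
    """A batch/longitudinal manifest is malformed."""


class DegeneratePatternError(ValueError):
    """Pattern carries no spatial signal (empty or constant mask); no
    variogram model can be fitted."""


class PlacementError(RuntimeError):
    """Synthetic lesion placement could not satisfy its constraints."""


class SmallPatternWarning(UserWarning):
    """Pattern has very few foreground voxels; variogram parameters are
    unstable (aliasing) and the standard distance may be inflated."""
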