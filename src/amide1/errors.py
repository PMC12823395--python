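"""Exception hierarchy shared across the package."""


class Amide1Error(Exception):
    """Base class for all package-specific errors."""


class GridError(Amide1Error):
    """Wavenumber grid is non-uniform, mismatched, or otherwise invalid."""


class FormatError(Amide1Error):
    """An input file does not conform to the expected table/image layout."""


class ParameterError(Amide1Error):
    """A parameter is outside its valid range."""


class StageError(Amide1Error):
    """A processing stage failed for a specific record."""


class PlacementError(Amide1Error):
    """Synthetic cell placement failed (disks could not be kept disjoint)."""
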