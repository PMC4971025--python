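"""Exception hierarchy for atlasdust."""


class AtlasDustError(Exception):
    """Base class for all atlasdust errors."""


class VolumeFormatError(AtlasDustError):
    """A file could not be read or written as a supported 3D volume."""


class LabelTypeError(AtlasDustError):
    """A volume presented as a label map does not hold integral label IDs."""


class GeometryMismatchError(AtlasDustError):
    """Two volumes that must share a voxel grid do not."""


class StaleIslandError(AtlasDustError):
    """An IslandRecord no longer matches the current label volume."""


class NoBorderError(AtlasDustError):
    """A region has no border voxels (it fills the entire grid)."""


class PlacementError(AtlasDustError):
    """A phantom defect could not be placed after bounded retries."""
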