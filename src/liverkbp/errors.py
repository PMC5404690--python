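"""Exception hierarchy for liverkbp."""


class LiverKBPError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(LiverKBPError):
    """Invalid voxel geometry (empty/full masks, PTV outside grid, ...)."""


class DimensionError(LiverKBPError):
    """Grids or arrays whose shapes/axes do not line up."""


class CapabilityError(LiverKBPError):
    """A prediction output was requested that the chosen method cannot produce.

    The capability matrix is: OVH regression predicts only V_<15Gy; scalar
    SVDL (median/mean/mode) predicts V_<15Gy, DVH and 3D dose; the fitting
    SVDL variants (skew-normal, non-parametric) predict V_<15Gy and DVH but
    not 3D dose.
    """


class DegenerateFitError(LiverKBPError):
    """A regression or distribution fit has no unique solution."""


class CohortError(LiverKBPError):
    """Problems with cohort composition or manifests (missing files, dupes)."""
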