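"""Exception hierarchy for cavcsg."""


class CavCsgError(Exception):
    """Base class for all cavcsg errors."""


class MeshFormatError(CavCsgError):
    """A mesh file could not be parsed.

    Carries the 1-based line number at which parsing failed, when known.
    """

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        if prefix:
            message = f"{prefix}: {message}"
        super().__init__(message)


class OpenMeshError(CavCsgError):
    """An operation requiring a closed (watertight) mesh received an open one."""


class GrazingRayError(CavCsgError):
    """A ray repeatedly grazed edges/vertices; no generic direction was found."""


class ResourceError(CavCsgError):
    """A lattice would exceed the configured memory budget; use coarser spacing."""


class DegenerateHullError(CavCsgError):
    """Convex hull input was degenerate (coincident/collinear sphere centers)."""


class NoCavityError(CavCsgError):
    """Cavity extraction produced an empty region."""


class EmptySubsiteError(CavCsgError):
    """Subsite carving produced an empty region (spheres miss the cavity)."""


class UndefinedSimilarityError(CavCsgError):
    """Volumetric similarity is undefined for a zero-volume operand."""
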