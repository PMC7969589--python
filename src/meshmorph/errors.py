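"""Exception hierarchy shared across the package."""


class MeshMorphError(Exception):
    """Base class for all meshmorph errors."""


class ParameterError(MeshMorphError, ValueError):
    """A parameter is outside its documented range or non-finite."""


class FormatError(MeshMorphError, ValueError):
    """A file does not parse under the named dialect."""


class ConsistencyError(MeshMorphError, ValueError):
    """Inputs that must agree (landmark counts, vertex correspondence) do not."""


class EmptyInputError(MeshMorphError, ValueError):
    """An operation received an empty mask, mesh or point set."""


class NoSurfaceError(MeshMorphError, ValueError):
    """A mask has no isosurface (empty or completely full)."""


class DegenerateInputError(MeshMorphError, ValueError):
    """A geometric configuration is rank-deficient (collinear, coplanar, zero variance)."""


class PipelineError(MeshMorphError, RuntimeError):
    """A pipeline stage failed or is missing its inputs."""
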