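"""Exception hierarchy shared across the toolkit."""


class DentoproxyError(Exception):
    """Base class for all toolkit errors."""


class FormatError(DentoproxyError):
    """A file could not be parsed in the declared format."""


class LatticeError(FormatError):
    """XYZ points do not lie on a regular rectangular lattice."""


class EmptyDataError(DentoproxyError):
    """An input carries no usable measurements."""


class WatertightError(DentoproxyError):
    """A mesh has boundary loops where a closed surface is required.

    ``loops`` holds the offending boundary loops as lists of vertex indices.
    """

    def __init__(self, message: str, loops=None):
        super().__init__(message)
        self.loops = loops or []


class LevelingError(DentoproxyError):
    """Plane leveling is degenerate (collinear or insufficient support)."""
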