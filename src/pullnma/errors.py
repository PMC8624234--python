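"""Exception and warning types shared across the package."""


class PullnmaError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(PullnmaError):
    """A PDB file could not be parsed."""


class EmptyStructureError(PullnmaError):
    """A structure or selection contains no usable atoms."""


class SelectionError(PullnmaError):
    """A residue-range selection does not resolve against the model."""


class DegenerateGeometryError(PullnmaError):
    """Coordinates are geometrically degenerate for the requested operation."""


class InsufficientModesError(PullnmaError):
    """An operation needs the complete non-zero mode spectrum but got a partial one."""


class ZeroModeSeparationError(PullnmaError):
    """The spectral gap between rigid-body and internal modes is too small to trust."""


class ConfigError(PullnmaError):
    """A run configuration is invalid."""


class DisconnectedNetworkWarning(UserWarning):
    """The elastic-network contact graph has more than one connected component."""


class MissingAtomWarning(UserWarning):
    """A residue was skipped because it lacks the atom needed for coarse-graining."""


class FallbackVolumeWarning(UserWarning):
    """A residue name was absent from the volume table and a fallback volume was used."""
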