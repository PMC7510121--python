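"""Exception hierarchy shared across the package."""


class BeadQuantError(Exception):
    """Base class for all package-specific failures."""


class FormatError(BeadQuantError, ValueError):
    """A file or in-memory object violates an expected data layout."""


class ParameterError(BeadQuantError, ValueError):
    """An operation received parameters outside its documented domain."""


class GenerationError(BeadQuantError, RuntimeError):
    """The synthetic-scene generator could not satisfy its constraints."""


class BackendContractError(BeadQuantError, RuntimeError):
    """A segmentation backend returned objects violating the tile contract."""
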