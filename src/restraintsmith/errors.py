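"""Exception hierarchy shared across the package."""


class RestraintsmithError(Exception):
    """Base class for all package errors."""


class SchemaError(RestraintsmithError):
    """A dictionary file violates the monomer-library schema."""


class ModApplicationError(RestraintsmithError):
    """A chemical modification could not be applied to a monomer definition."""


class ModelError(RestraintsmithError):
    """An atomic model is malformed or inconsistent with the library."""


class FormatError(RestraintsmithError):
    """A coordinate file could not be parsed or written in the requested format."""


class LinkIdentificationError(RestraintsmithError):
    """A named link could not be resolved against the loaded dictionaries."""
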