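"""Exception hierarchy.

``InputError`` covers unreadable or malformed input files (CLI exit code 2),
``ValidationError`` covers inputs that parse but violate pipeline
preconditions, e.g. partial models (exit code 3); everything else is an
internal error (exit code 4).
"""


class ResqaError(Exception):
    """Base class for package errors."""


class InputError(ResqaError):
    """Malformed or unreadable input file."""


class PdbFormatError(InputError):
    """PDB file could not be parsed."""


class EmptyStructureError(InputError):
    """No parsable residues in the structure file."""


class ValidationError(ResqaError):
    """Input parsed but violates a pipeline precondition."""


class IncompleteModelError(ValidationError):
    """Model lacks coordinates for some target residues and was rejected."""


class FeatureError(ResqaError):
    """Structure lacks atoms needed to derive a feature."""
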