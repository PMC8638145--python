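"""Exception hierarchy.

``InputError`` (and subclasses) map to exit code 1 in the CLI; anything
else that escapes maps to exit code 2.
"""


class ProlaminError(Exception):
    """Base class for all package errors."""


class InputError(ProlaminError):
    """Invalid user-supplied data (bad file, empty input, bad residues)."""


class FormatError(InputError):
    """A file does not conform to its declared format (FASTA/GFF3/TSV)."""


class CoordinateError(InputError):
    """A genomic coordinate falls outside the sequence it refers to."""


class ParameterError(InputError):
    """A tuning parameter is outside its documented range."""


class SpecError(InputError):
    """A synthetic-genome specification is internally inconsistent."""
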