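"""Exception hierarchy shared by all asvpost stages.

Every error raised on bad user input derives from :class:`AsvpostError`
so the command-line layer can map them to a single data-error exit code.
"""


class AsvpostError(Exception):
    """Base class for all asvpost data and usage errors."""


class DataFormatError(AsvpostError, ValueError):
    """A file could be read but its contents violate the expected format
    (e.g. a non-integer or negative count cell)."""


class ConsistencyError(AsvpostError, ValueError):
    """Two components of a dataset disagree (e.g. FASTA IDs not matching
    the feature-table IDs, or mismatched matrix shapes)."""
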