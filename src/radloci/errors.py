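"""Exception hierarchy for radloci.

Every error raised by the package derives from :class:`RadlociError`, so
callers (including the CLI) can catch one type and report the stage that
failed.
"""


class RadlociError(Exception):
    """Base class for all radloci errors."""


class NamingConventionError(RadlociError):
    """A sample file does not follow the ``<POP>_<ID>.F.fq`` convention."""


class PairingError(RadlociError):
    """A forward file has no matching reverse file (or vice versa)."""


class TruncationError(RadlociError):
    """Paired FASTQ files disagree on record count."""


class FormatError(RadlociError):
    """Malformed FASTQ/FASTA/VCF content."""


class AlphabetError(RadlociError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class EmptySelectionError(RadlociError):
    """A coverage cutoff removed every unique read; advise a lower cutoff."""
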