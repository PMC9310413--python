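"""Exception hierarchy.

Exit-code mapping used by the command line layer: usage/configuration
problems exit 2, data corruption exits 3, a mismatched reference genome
exits 4.
"""


class SgcError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SgcError):
    """Malformed FASTA input.

    Carries the byte offset at which parsing failed.
    """

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (byte offset {offset})"
        super().__init__(message)
        self.offset = offset


class CorruptionError(SgcError):
    """Archive or serialized stream is damaged or inconsistent."""


class WrongReferenceError(SgcError):
    """The reference genome supplied at decompression does not match the
    one the archive was built against."""


class ConfigurationError(SgcError):
    """Invalid parameter combination or unknown backend."""
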