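"""Exception hierarchy shared across the package."""


class SeqTuplesError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(SeqTuplesError):
    """Raised when a FASTA file cannot be parsed."""


class ValidationError(SeqTuplesError):
    """Raised when input data violates a contract (alphabet, ids, labels)."""


class ConfigurationError(SeqTuplesError):
    """Raised when a configuration object is internally inconsistent."""


class RecordParseError(SeqTuplesError):
    """Raised when a mutation-record string cannot be tokenized.

    Carries the index of the offending token in ``token_index``.
    """

    def __init__(self, message: str, token_index: int):
        super().__init__(f"{message} (token {token_index})")
        self.token_index = token_index
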