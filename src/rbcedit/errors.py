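"""Exception hierarchy shared across the package."""


class RbcEditError(Exception):
    """Base class for all package errors."""


class AlphabetError(RbcEditError, ValueError):
    """A sequence or symbol is outside the allowed nucleotide alphabet."""


class ContractError(RbcEditError, ValueError):
    """A caller violated an operation precondition (lengths, labels, ranges)."""


class DataError(RbcEditError, ValueError):
    """Input data is inconsistent (e.g. REF allele disagrees with the reference)."""


class GenerationError(RbcEditError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class ValidationError(RbcEditError, ValueError):
    """Configuration validation failed; ``errors`` lists every failure."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
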