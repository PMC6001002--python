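"""Exception hierarchy shared across the package.

``RecfineError`` subclasses map to CLI exit code 2 (validation / input
problems); plain ``OSError`` maps to exit code 3 (I/O).
"""


class RecfineError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RecfineError):
    """A file does not conform to its declared format (bad header, missing
    column, unparsable line)."""


class RecordError(RecfineError):
    """A single record is invalid (non-ACGT allele, bad genotype, ...)."""


class ValidationError(RecfineError):
    """A domain object violates its invariants."""


class ReferenceMismatchError(RecfineError):
    """A variant's REF allele disagrees with the reference sequence."""


class MissingAnnotationError(RecfineError):
    """A variant reached an impact-aware step without consequences."""


class DegenerateInputError(RecfineError):
    """An operation received input it cannot meaningfully process
    (e.g. zero evaluable windows for a genome baseline)."""


class AmpliconNotFoundError(RecfineError):
    """Primer pair produced no product on the template."""


class AmbiguousProductError(RecfineError):
    """Primer pair produced more than one product; loci are attached."""

    def __init__(self, message: str, loci=None):
        super().__init__(message)
        self.loci = list(loci or [])
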