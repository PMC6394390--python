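"""Exception hierarchy used across the package."""


class PepquantError(Exception):
    """Base class for all package errors."""


class InputError(PepquantError):
    """Missing files, unknown residues, bad user-supplied values."""


class FormatError(PepquantError):
    """A file exists but does not conform to its declared format."""


class ContractError(PepquantError):
    """A documented precondition of an operation was violated."""


class AlignmentInfeasibleError(PepquantError):
    """Too few shared peptides to fit a retention-time alignment."""
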