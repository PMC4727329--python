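"""Exception hierarchy shared across the pipeline."""


class OncophaseError(Exception):
    """Base class for all package-specific errors."""


class MatrixParseError(OncophaseError, ValueError):
    """A matrix cell could not be parsed as a number."""


class LabelError(OncophaseError, ValueError):
    """Duplicate or otherwise invalid row/column labels."""


class DomainError(OncophaseError, ValueError):
    """A value lies outside its documented domain (e.g. 0.5 in a binary matrix)."""


class AlignmentError(OncophaseError, ValueError):
    """Two matrices that must share sample labels (in order) do not."""


class SchemaError(OncophaseError, ValueError):
    """A tabular input is missing a required column."""


class ContractError(OncophaseError, ValueError):
    """A precondition of an operation was violated by the caller."""


class DegenerateInputError(OncophaseError, ValueError):
    """Input too small or too flat for the operation to be meaningful."""


class SolverError(OncophaseError, RuntimeError):
    """The MILP backend failed (infeasible model, no incumbent, ...)."""
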