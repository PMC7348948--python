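"""Exception hierarchy for funcresp."""


class FuncrespError(Exception):
    """Base class for all funcresp errors."""


class InvalidParameterError(FuncrespError, ValueError):
    """Functional-response parameters violate their domain (negative, non-finite)."""


class NumericalDomainError(FuncrespError, ArithmeticError):
    """A numerical routine was handed an argument outside its valid domain."""


class InvalidDesignError(FuncrespError, ValueError):
    """An experimental design table is empty, inconsistent, or mislabeled."""


class DegenerateDataError(FuncrespError, ValueError):
    """Data carry no information for the requested fit (e.g. zero total kills)."""


class InvalidComparisonError(FuncrespError, ValueError):
    """Two results cannot be compared (e.g. disjoint experimental density ranges)."""


class NoDrawsError(FuncrespError, ValueError):
    """A bootstrap result contains no successful draws."""


class TableParseError(FuncrespError, ValueError):
    """A trial table failed validation; message names the offending row/column."""
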