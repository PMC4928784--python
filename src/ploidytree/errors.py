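"""Exception hierarchy shared across the package."""


class PloidyTreeError(Exception):
    """Base class for all package errors."""


class InputError(PloidyTreeError):
    """Malformed or out-of-contract user input (CLI exit code 2)."""


class ContractError(PloidyTreeError):
    """A function was called outside its documented precondition."""


class InvariantError(PloidyTreeError):
    """An internal invariant was violated (CLI exit code 4)."""


class SolverTimeout(PloidyTreeError):
    """The MILP solver hit its time limit without proving optimality."""


class MismatchedPloidyError(PloidyTreeError):
    """An edge whose endpoints differ in ploidy by two or more.

    Such edges cannot be decomposed into unit ploidy steps and are
    ignored when tallying event types.
    """
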