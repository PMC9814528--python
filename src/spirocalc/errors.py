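"""Exception hierarchy.

Exit-code mapping used by the CLI: input/parse problems -> 2,
stoichiometry problems -> 3, fit non-convergence -> 4.
"""


class SpirocalcError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(SpirocalcError):
    """Invalid user input (bad constants, malformed tables, unknown units)."""

    exit_code = 2


class ParseError(InputError):
    """A text input (QM log, CSV) could not be parsed."""

    exit_code = 2


class StoichiometryError(SpirocalcError):
    """Open/closed complexes are not comparable (unbalanced explicit waters,
    mixed forms in an ensemble)."""

    exit_code = 3


class FitError(SpirocalcError):
    """Nonlinear fit failed to converge or too many bootstrap replicates diverged."""

    exit_code = 4
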