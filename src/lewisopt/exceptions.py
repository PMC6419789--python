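"""Exception hierarchy for lewisopt."""


class LewisoptError(Exception):
    """Base class for all lewisopt errors."""


class UnsupportedElement(LewisoptError):
    """An element without score-table coverage (outside H,C,N,O,F,P,S,Cl,Br)."""


class MalformedInput(LewisoptError):
    """Structurally invalid input (self-bond, duplicate bond, missing atom)."""


class InfeasibleMolecule(LewisoptError):
    """No complete electron assignment exists (negative budget or capacity shortfall)."""


class RadicalNotSupported(LewisoptError):
    """Odd number of electrons to place; open-shell species are rejected."""


class OverSaturatedAtom(LewisoptError):
    """An atom's sigma framework already exceeds its target valency."""


class KeyOverflow(LewisoptError):
    """Formal charge magnitude too large for the 4-bit key field."""


class InvalidBondState(LewisoptError):
    """Bond electron count outside the representable range."""


class ParseError(LewisoptError):
    """Malformed score-table or structure file."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MemoryLimitExceeded(LewisoptError):
    """A* priority-queue memory estimate exceeded the configured limit."""


class NoValidAssignment(LewisoptError):
    """Requested enumeration of minima but the minimum score is infinite."""
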