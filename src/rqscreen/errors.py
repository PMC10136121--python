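"""Exception hierarchy."""

from __future__ import annotations


class RQScreenError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RQScreenError, ValueError):
    """Malformed input text (FASTA, character-matrix TSV, Newick).

    ``line`` carries the 1-based line number when it is known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class InvalidSequenceError(RQScreenError, ValueError):
    """A sequence contains a symbol outside the accepted alphabet."""


class PanelError(RQScreenError, ValueError):
    """A marker panel violates its structural invariants."""


class UninformativeCharacterError(RQScreenError, ValueError):
    """A character has fewer than two observed tip states."""


class LedgerImbalanceError(RQScreenError, ValueError):
    """A pathway specification whose redox ledger cannot close."""

    def __init__(self, message: str, produced=None, consumed=None):
        super().__init__(message)
        self.produced = produced
        self.consumed = consumed
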