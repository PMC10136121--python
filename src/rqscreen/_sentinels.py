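"""Singleton sentinels shared across modules.

``MISSING`` marks an unobservable character-matrix cell or residue call
(no homolog, site outside the aligned span, or a "-" cell in a printed
matrix).  ``GAP`` marks a reference position that maps into a deletion in
the aligned target.  They are deliberately distinct objects so that
missing data is never conflated with alignment gaps.
"""

from __future__ import annotations


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return self._name

    def __reduce__(self):
        return (_lookup, (self._name,))


MISSING = _Sentinel("MISSING")
GAP = _Sentinel("GAP")

_REGISTRY = {"MISSING": MISSING, "GAP": GAP}


def _lookup(name: str) -> _Sentinel:
    return _REGISTRY[name]
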