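"""Readers and writers for the external formats the pipeline touches.

FASTA (protein or nucleotide), the species x diagnostic-site character
matrix as TSV (the dialect of the published residue table: one header row
of ``MARKER:position`` site labels, one row per species, ``-`` for a
missing observation), and Newick trees (via dendropy).

The FASTA reader is deliberately strict — an empty sequence under a
header or sequence text before the first header is a :class:`ParseError`
carrying the offending line number — because downstream residue calls are
only meaningful on complete records.
"""

from __future__ import annotations

import csv
import io as _stdio
import os
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import dendropy

from ._sentinels import MISSING
from .errors import ParseError

__all__ = [
    "SequenceRecord",
    "CharacterMatrix",
    "MISSING",
    "read_fasta",
    "write_fasta",
    "read_character_matrix",
    "write_character_matrix",
    "read_newick",
    "write_newick",
]

#: Missing-data token used in the TSV dialect (matches the printed table).
MISSING_TOKEN = "-"

_AA_CODES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record.

    ``id`` is the first whitespace-delimited token of the header;
    ``description`` is the remainder.  The sequence is uppercased and
    holds no internal whitespace.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"SequenceRecord {self.id!r}: empty sequence")
        seq = "".join(self.sequence.split()).upper()
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def _as_text_handle(source) -> tuple[TextIO, bool]:
    """Return (handle, should_close)."""
    if hasattr(source, "read"):
        return source, False
    return open(os.fspath(source), "rt"), True


def read_fasta(source) -> list[SequenceRecord]:
    """Parse FASTA text from a path or open text handle.

    Wrapped sequence lines are concatenated and uppercased; record order
    is preserved.  Raises :class:`ParseError` (with the line number) on
    sequence text before the first header or an empty sequence under a
    header.
    """
    handle, close = _as_text_handle(source)
    try:
        records: list[SequenceRecord] = []
        header: str | None = None
        header_line = 0
        chunks: list[str] = []

        def _flush(at_line: int) -> None:
            if header is None:
                return
            seq = "".join(chunks)
            if not seq:
                raise ParseError(
                    f"empty sequence for record {header.split()[0]!r}", line=at_line
                )
            fid, _, desc = header.partition(" ")
            records.append(SequenceRecord(id=fid, sequence=seq, description=desc.strip()))

        lineno = 0
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(at_line=header_line)
                header = line[1:].strip()
                if not header:
                    raise ParseError("empty FASTA header", line=lineno)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError("sequence data before first '>' header", line=lineno)
                chunks.append("".join(line.split()).upper())
        if header is None:
            raise ParseError("no FASTA records found", line=lineno or 1)
        _flush(at_line=header_line)
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], dest=None, width: int = 60) -> str:
    """Serialize records to FASTA text (and optionally to ``dest``)."""
    if width < 1:
        raise ValueError("width must be positive")
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    out = _stdio.StringIO()
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        out.write(f">{header}\n")
        for start in range(0, len(rec.sequence), width):
            out.write(rec.sequence[start : start + width] + "\n")
    text = out.getvalue()
    if dest is not None:
        handle, close = (dest, False) if hasattr(dest, "write") else (open(os.fspath(dest), "wt"), True)
        try:
            handle.write(text)
        finally:
            if close:
                handle.close()
    return text


@dataclass(frozen=True)
class CharacterMatrix:
    """Species x diagnostic-site state table.

    ``states[i][j]`` is the one-letter residue observed for species ``i``
    at site ``j``, or the :data:`MISSING` sentinel.  Site labels follow
    the ``MARKER:position`` convention with 1-based reference-protein
    coordinates (e.g. ``COQ2:204``).
    """

    species: tuple[str, ...]
    sites: tuple[str, ...]
    states: tuple[tuple[object, ...], ...] = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "states", tuple(tuple(r) for r in self.states))
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names in character matrix")
        for name, row in zip(self.species, self.states, strict=True):
            if len(row) != len(self.sites):
                raise ValueError(
                    f"row for {name!r} has {len(row)} cells, expected {len(self.sites)}"
                )
            for label, state in zip(self.sites, row):
                if state is MISSING:
                    continue
                if not (isinstance(state, str) and len(state) == 1 and state in _AA_CODES):
                    raise ValueError(
                        f"invalid state {state!r} for {name!r} at {label}"
                    )

    def row(self, species: str) -> dict[str, object]:
        i = self.species.index(species)
        return dict(zip(self.sites, self.states[i]))

    def to_frame(self):
        import pandas as pd

        data = [
            [MISSING_TOKEN if s is MISSING else s for s in row] for row in self.states
        ]
        return pd.DataFrame(data, index=list(self.species), columns=list(self.sites))


def read_character_matrix(source) -> CharacterMatrix:
    """Read the TSV character-matrix dialect.

    Header row: ``species`` (or any label) followed by site labels.
    Cells are single residue letters or ``-`` for missing.  Ragged rows
    and multi-letter cells are parse errors.
    """
    handle, close = _as_text_handle(source)
    try:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty character-matrix file", line=1) from None
        if len(header) < 2:
            raise ParseError("header must contain at least one site label", line=1)
        sites = tuple(h.strip() for h in header[1:])
        species: list[str] = []
        rows: list[tuple[object, ...]] = []
        for lineno, cells in enumerate(reader, start=2):
            if not cells or (len(cells) == 1 and not cells[0].strip()):
                continue
            if len(cells) != len(sites) + 1:
                raise ParseError(
                    f"ragged row: {len(cells)} fields, expected {len(sites) + 1}",
                    line=lineno,
                )
            name = cells[0].strip()
            if not name:
                raise ParseError("empty species name", line=lineno)
            row: list[object] = []
            for label, cell in zip(sites, cells[1:]):
                cell = cell.strip()
                if cell == MISSING_TOKEN:
                    row.append(MISSING)
                elif len(cell) == 1:
                    row.append(cell.upper())
                else:
                    raise ParseError(
                        f"cell {cell!r} at {label} is not a single residue or "
                        f"{MISSING_TOKEN!r}",
                        line=lineno,
                    )
            species.append(name)
            rows.append(tuple(row))
        try:
            return CharacterMatrix(tuple(species), sites, tuple(rows))
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
    finally:
        if close:
            handle.close()


def write_character_matrix(matrix: CharacterMatrix, dest=None, species_header: str = "species") -> str:
    lines = ["\t".join([species_header, *matrix.sites])]
    for name, row in zip(matrix.species, matrix.states):
        cells = [MISSING_TOKEN if s is MISSING else str(s) for s in row]
        lines.append("\t".join([name, *cells]))
    text = "\n".join(lines) + "\n"
    if dest is not None:
        handle, close = (dest, False) if hasattr(dest, "write") else (open(os.fspath(dest), "wt"), True)
        try:
            handle.write(text)
        finally:
            if close:
                handle.close()
    return text


def read_newick(source) -> dendropy.Tree:
    """Parse a Newick tree (string, path, or handle); tip names preserved.

    Branch lengths are stored but ignored by the parsimony machinery.
    Duplicate tip names and unbalanced parentheses are parse errors.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "(" not in text and os.path.exists(text):
            with open(text) as fh:
                text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate tip names: {', '.join(dupes)}")
    if not labels:
        raise ParseError("tree has no named tips")
    tree.is_rooted = True  # parsimony traversals treat the seed node as root
    return tree


def write_newick(tree: dendropy.Tree, dest=None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    text = text.strip() + "\n"
    if dest is not None:
        handle, close = (dest, False) if hasattr(dest, "write") else (open(os.fspath(dest), "wt"), True)
        try:
            handle.write(text)
        finally:
            if close:
                handle.close()
    return text
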