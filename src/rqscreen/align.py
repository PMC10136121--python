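"""Pairwise protein alignment and six-frame translation.

Global (Needleman-Wunsch) and local (Smith-Waterman) alignment with
affine gap costs under BLOSUM62, plus the reference->target position map
used to read diagnostic residues off a homolog, and six-frame translation
so nucleotide contigs can be searched the way tblastn searches them.

Scoring model
-------------
A gap of length ``k`` costs ``gap_open + (k - 1) * gap_extend`` (defaults
-11 / -1, the conventional protein-BLAST parameterisation).  ``X`` (the
translation of ambiguous codons) scores 0 against every residue.  The
dynamic program is the three-matrix Gotoh recursion; traceback ties are
broken diagonal > up (gap in target) > left (gap in reference) so output
is deterministic.

The inner fill loops are JIT-compiled with numba; everything else is
plain Python.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from ._sentinels import GAP
from .errors import InvalidSequenceError

__all__ = [
    "AlignParams",
    "Alignment",
    "PositionMap",
    "GAP",
    "global_align",
    "local_align",
    "map_positions",
    "score_alignment",
    "six_frame_translate",
    "PeptideSegment",
    "reverse_complement",
    "AA_ALPHABET",
]

#: 20 standard residues plus X (ambiguous); order fixes the matrix layout.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_NT_ALPHABET = set("ACGTN")

_NEG = -(2**40)


def _build_submat(name: str) -> np.ndarray:
    table = substitution_matrices.load(name)
    k = len(AA_ALPHABET)
    sub = np.zeros((k, k), dtype=np.int64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            if a == "X" or b == "X":
                sub[i, j] = 0  # ambiguous residue is scored neutrally
            else:
                sub[i, j] = int(table[a, b])
    return sub


_MATRICES: dict[str, np.ndarray] = {}


def substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    if name not in _MATRICES:
        _MATRICES[name] = _build_submat(name)
    return _MATRICES[name]


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters: substitution matrix and affine gap costs."""

    matrix: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError(
                f"require gap_open <= gap_extend < 0, got "
                f"open={self.gap_open}, extend={self.gap_extend}"
            )
        substitution_matrix(self.matrix)  # fail fast on unknown matrix

    @property
    def submat(self) -> np.ndarray:
        return substitution_matrix(self.matrix)


DEFAULT_PARAMS = AlignParams()


def encode_protein(seq: str, what: str = "sequence") -> np.ndarray:
    """Map a protein string to matrix indices, validating the alphabet."""
    if not seq:
        raise InvalidSequenceError(f"empty {what}")
    out = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        idx = _AA_INDEX.get(ch)
        if idx is None:
            raise InvalidSequenceError(
                f"invalid residue {ch!r} at position {i + 1} of {what}"
            )
        out[i] = idx
    return out


@dataclass(frozen=True)
class Alignment:
    """A scored pairwise alignment.

    ``aligned_ref``/``aligned_target`` are equal-length strings with
    ``-`` gap characters; removing gaps recovers the aligned
    (sub)sequences.  For local mode, ``ref_span``/``target_span`` give
    the 1-based inclusive coordinates covered in each input (``None``
    for an empty alignment).
    """

    aligned_ref: str
    aligned_target: str
    score: int
    mode: str
    ref_span: tuple[int, int] | None
    target_span: tuple[int, int] | None

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_target):
            raise ValueError("aligned strings differ in length")

    @property
    def columns(self) -> int:
        return len(self.aligned_ref)

    def identity_fraction(self) -> float:
        """Identical residue pairs over columns where both rows are residues."""
        pairs = [
            (a, b)
            for a, b in zip(self.aligned_ref, self.aligned_target)
            if a != "-" and b != "-"
        ]
        if not pairs:
            return 0.0
        return sum(a == b for a, b in pairs) / len(pairs)


def score_alignment(aligned_ref: str, aligned_target: str, params: AlignParams = DEFAULT_PARAMS) -> int:
    """Recompute an alignment's score from its aligned strings.

    Substitution terms for residue-residue columns plus
    ``gap_open + (k-1)*gap_extend`` per maximal gap run in either row.
    Used as a self-consistency check on every alignment the DP emits.
    """
    sub = params.submat
    score = 0
    for row in (aligned_ref, aligned_target):
        run = 0
        for ch in row:
            if ch == "-":
                run += 1
            else:
                if run:
                    score += params.gap_open + (run - 1) * params.gap_extend
                run = 0
        if run:
            score += params.gap_open + (run - 1) * params.gap_extend
    for a, b in zip(aligned_ref, aligned_target):
        if a != "-" and b != "-":
            score += int(sub[_AA_INDEX[a], _AA_INDEX[b]])
    return score


@njit(cache=True)
def _fill_global(a, b, sub, go, ge):  # pragma: no cover - exercised via callers
    n = a.shape[0]
    m = b.shape[0]
    NEG = -(2**40)
    M = np.full((n + 1, m + 1), NEG, np.int64)
    X = np.full((n + 1, m + 1), NEG, np.int64)
    Y = np.full((n + 1, m + 1), NEG, np.int64)
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p
            best = M[i - 1, j] + go
            p = 0
            if X[i - 1, j] + ge > best:
                best = X[i - 1, j] + ge
                p = 1
            if Y[i - 1, j] + go > best:
                best = Y[i - 1, j] + go
                p = 2
            X[i, j] = best
            pX[i, j] = p
            best = M[i, j - 1] + go
            p = 0
            if X[i, j - 1] + go > best:
                best = X[i, j - 1] + go
                p = 1
            if Y[i, j - 1] + ge > best:
                best = Y[i, j - 1] + ge
                p = 2
            Y[i, j] = best
            pY[i, j] = p
    return M, X, Y, pM, pX, pY


@njit(cache=True)
def _fill_local(a, b, sub, go, ge):  # pragma: no cover - exercised via callers
    n = a.shape[0]
    m = b.shape[0]
    NEG = -(2**40)
    M = np.full((n + 1, m + 1), NEG, np.int64)
    X = np.full((n + 1, m + 1), NEG, np.int64)
    Y = np.full((n + 1, m + 1), NEG, np.int64)
    pM = np.zeros((n + 1, m + 1), np.uint8)
    pX = np.zeros((n + 1, m + 1), np.uint8)
    pY = np.zeros((n + 1, m + 1), np.uint8)
    best_score = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            if best < 0:
                best = 0
                p = 3  # fresh start of a local alignment
            M[i, j] = best + s
            pM[i, j] = p
            if M[i, j] > best_score:
                best_score = M[i, j]
                bi = i
                bj = j
            best = M[i - 1, j] + go
            p = 0
            if X[i - 1, j] + ge > best:
                best = X[i - 1, j] + ge
                p = 1
            if Y[i - 1, j] + go > best:
                best = Y[i - 1, j] + go
                p = 2
            X[i, j] = best
            pX[i, j] = p
            best = M[i, j - 1] + go
            p = 0
            if X[i, j - 1] + go > best:
                best = X[i, j - 1] + go
                p = 1
            if Y[i, j - 1] + ge > best:
                best = Y[i, j - 1] + ge
                p = 2
            Y[i, j] = best
            pY[i, j] = p
    return M, X, Y, pM, pX, pY, best_score, bi, bj


def _traceback(a, b, pM, pX, pY, i, j, state, stop_at_start=False):
    """Follow pointer matrices back; returns aligned strings and start cell."""
    ref: list[str] = []
    tgt: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            p = pM[i, j]
            if stop_at_start and p == 3:
                ref.append(a[i - 1])
                tgt.append(b[j - 1])
                i -= 1
                j -= 1
                break
            ref.append(a[i - 1])
            tgt.append(b[j - 1])
            i -= 1
            j -= 1
            state = p
        elif state == 1:  # X: gap in target, consumes reference
            p = pX[i, j]
            ref.append(a[i - 1])
            tgt.append("-")
            i -= 1
            state = p
        else:  # Y: gap in reference, consumes target
            p = pY[i, j]
            ref.append("-")
            tgt.append(b[j - 1])
            j -= 1
            state = p
    return "".join(reversed(ref)), "".join(reversed(tgt)), i, j


def global_align(a: str, b: str, params: AlignParams = DEFAULT_PARAMS) -> Alignment:
    """Optimal global alignment of protein ``a`` (reference) vs ``b`` (target)."""
    ea = encode_protein(a, "reference")
    eb = encode_protein(b, "target")
    M, X, Y, pM, pX, pY = _fill_global(
        ea, eb, params.submat, np.int64(params.gap_open), np.int64(params.gap_extend)
    )
    n, m = len(a), len(b)
    scores = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(scores))  # argmax takes the first max: M > X > Y
    score = int(scores[state])
    ar, at, _, _ = _traceback(a, b, pM, pX, pY, n, m, state)
    return Alignment(
        aligned_ref=ar,
        aligned_target=at,
        score=score,
        mode="global",
        ref_span=(1, n),
        target_span=(1, m),
    )


def local_align(a: str, b: str, params: AlignParams = DEFAULT_PARAMS) -> Alignment:
    """Optimal local alignment; score floored at 0 (empty alignment)."""
    ea = encode_protein(a, "reference")
    eb = encode_protein(b, "target")
    M, X, Y, pM, pX, pY, best, bi, bj = _fill_local(
        ea, eb, params.submat, np.int64(params.gap_open), np.int64(params.gap_extend)
    )
    if best <= 0:
        return Alignment("", "", 0, "local", None, None)
    ar, at, i0, j0 = _traceback(a, b, pM, pX, pY, int(bi), int(bj), 0, stop_at_start=True)
    return Alignment(
        aligned_ref=ar,
        aligned_target=at,
        score=int(best),
        mode="local",
        ref_span=(i0 + 1, int(bi)),
        target_span=(j0 + 1, int(bj)),
    )


class PositionMap(Mapping):
    """1-based reference position -> 1-based target position or :data:`GAP`.

    Only reference positions inside the alignment's reference span are in
    the map's domain; mapped (non-GAP) values are strictly increasing.
    """

    def __init__(self, mapping: dict[int, object]):
        self._map = dict(mapping)

    def __getitem__(self, ref_pos: int):
        return self._map[ref_pos]

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self._map))

    def __len__(self) -> int:
        return len(self._map)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PositionMap({self._map!r})"


def map_positions(aln: Alignment) -> PositionMap:
    """Column-wise reference->target coordinate map of an alignment."""
    if aln.ref_span is None:
        return PositionMap({})
    ref_pos = aln.ref_span[0] - 1
    tgt_pos = aln.target_span[0] - 1 if aln.target_span else 0
    mapping: dict[int, object] = {}
    for ra, ta in zip(aln.aligned_ref, aln.aligned_target):
        if ta != "-":
            tgt_pos += 1
        if ra != "-":
            ref_pos += 1
            mapping[ref_pos] = tgt_pos if ta != "-" else GAP
    return PositionMap(mapping)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class PeptideSegment:
    """A stop-free peptide from one reading frame of a contig.

    ``frame`` is +1/+2/+3 (forward strand) or -1/-2/-3 (reverse
    complement); ``nt_start`` is the 1-based position, on the strand as
    read, of the first base of the segment's first codon.
    """

    frame: int
    nt_start: int
    peptide: str


def six_frame_translate(seq: str, min_length: int = 1) -> list[PeptideSegment]:
    """Translate a nucleotide sequence in all six frames.

    Standard genetic code; ``N`` translates to ``X``; peptides are split
    at stop codons.  Segments shorter than ``min_length`` are dropped.
    """
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in _NT_ALPHABET:
            raise InvalidSequenceError(
                f"invalid nucleotide {ch!r} at position {i + 1}"
            )
    segments: list[PeptideSegment] = []
    strands = {1: seq, -1: reverse_complement(seq)}
    for sign, strand_seq in strands.items():
        for offset in range(3):
            frame = sign * (offset + 1)
            coding = strand_seq[offset:]
            coding = coding[: len(coding) - len(coding) % 3]
            if not coding:
                continue
            peptide = str(Seq(coding).translate())
            start = 0
            for piece in peptide.split("*"):
                if len(piece) >= min_length and piece:
                    segments.append(
                        PeptideSegment(
                            frame=frame,
                            nt_start=offset + 3 * start + 1,
                            peptide=piece,
                        )
                    )
                start += len(piece) + 1
    return segments
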