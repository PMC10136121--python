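"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and Fitch code
paths: alignment scores come from explicit enumeration over the alignment
space (scored straight from the BLOSUM62 table published with biopython),
and parsimony lengths come from exhaustive minimisation over all internal
node labelings.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def pair_score(a: str, b: str) -> int:
    if a == "X" or b == "X":
        return 0
    return int(_B62[a, b])


def brute_force_global(a: str, b: str, gap_open: int = -11, gap_extend: int = -1) -> int:
    """Max score over every global alignment, by full path enumeration."""
    best = [-(10**9)]

    def step(i: int, j: int, prev: str, score: int) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            step(i + 1, j + 1, "D", score + pair_score(a[i], b[j]))
        if i < len(a):
            step(i + 1, j, "U", score + (gap_extend if prev == "U" else gap_open))
        if j < len(b):
            step(i, j + 1, "L", score + (gap_extend if prev == "L" else gap_open))

    step(0, 0, "", 0)
    return best[0]


def brute_force_local(a: str, b: str, gap_open: int = -11, gap_extend: int = -1) -> int:
    """Max over all alignments of all substring pairs, floored at 0.

    Exhaustive search of the local-alignment space written as a memoised
    recursion over (position, previous move); paths may start at any
    residue pair and stop anywhere.
    """

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, prev: str) -> int:
        best = 0  # stopping here is always allowed
        if i < len(a) and j < len(b):
            cand = pair_score(a[i], b[j]) + ext(i + 1, j + 1, "D")
            if cand > best:
                best = cand
        if i < len(a):
            cand = (gap_extend if prev == "U" else gap_open) + ext(i + 1, j, "U")
            if cand > best:
                best = cand
        if j < len(b):
            cand = (gap_extend if prev == "L" else gap_open) + ext(i, j + 1, "L")
            if cand > best:
                best = cand
        return best

    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            cand = pair_score(a[i], b[j]) + ext(i + 1, j + 1, "D")
            if cand > best:
                best = cand
    return best


def brute_force_local_enum(a: str, b: str, gap_open: int = -11, gap_extend: int = -1) -> int:
    """Pure-enumeration local oracle (tiny inputs only): max global score
    over every substring pair."""
    best = 0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            s = brute_force_global(a[i1:i2], b[j1:j2], gap_open, gap_extend)
            if s > best:
                best = s
    return best


def exhaustive_parsimony(tree, character: dict[str, str], alphabet) -> int:
    """Minimum number of state changes over all labelings of the internal
    nodes (and of tips with unknown state)."""
    alphabet = sorted(alphabet)
    nodes = list(tree.preorder_node_iter())
    free = []
    fixed = {}
    for node in nodes:
        if node.is_leaf():
            state = character.get(node.taxon.label if node.taxon else None, "?")
            if state == "?":
                free.append(node)
            else:
                fixed[id(node)] = state
        else:
            free.append(node)
    best = 10**9
    for assignment in itertools.product(alphabet, repeat=len(free)):
        states = dict(fixed)
        for node, state in zip(free, assignment):
            states[id(node)] = state
        cost = 0
        for node in nodes:
            parent = node.parent_node
            if parent is not None and states[id(node)] != states[id(parent)]:
                cost += 1
        if cost < best:
            best = cost
    return best


def random_newick(rng, n_tips: int, prefix: str = "T") -> str:
    """Random rooted binary topology by repeated joins."""
    subtrees = [f"{prefix}{i}" for i in range(n_tips)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        subtrees.append(f"({left},{right})")
    return subtrees[0] + ";"


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
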