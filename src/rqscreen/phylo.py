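"""Fitch-parsimony ancestral-state reconstruction of marker characters.

Whether the common ancestor of a clade (e.g. cnidarians) had
facultatively anaerobic mitochondria can be asked formally by mapping the
diagnostic-residue states onto a species tree and reconstructing ancestral
states.  This module implements unordered, equal-cost (Fitch) parsimony:
a bottom-up pass of set intersections/unions (each union is one implied
state change) and a top-down pass that resolves preferred node states by
intersection with the parent.  Missing observations enter as ``?`` and
contribute the full state alphabet; branch lengths are ignored.

Topology is a user input — the order of divergence among early-diverging
animal groups is itself debated — so reconstructions are reported per
supplied tree rather than on any fixed topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from ._sentinels import MISSING
from .errors import UninformativeCharacterError
from .io import CharacterMatrix
from .markers import MarkerDefinition, default_panel, site_label

__all__ = [
    "UNKNOWN",
    "encode_characters",
    "fitch",
    "reconstruct_all",
    "AncestralReconstruction",
    "annotated_newick",
]

#: Token for an unobserved tip state (full state set under parsimony).
UNKNOWN = "?"


def encode_characters(
    matrix: CharacterMatrix,
    panel: Sequence[MarkerDefinition] | None = None,
    mode: str = "binary",
) -> dict[str, dict[str, str]]:
    """Per-site character vectors from a state matrix.

    ``binary`` mode scores each site 1 if the observed residue equals the
    panel's anaerobic residue and 0 otherwise; ``residue`` mode keeps the
    raw amino-acid letters.  MISSING becomes ``?`` in both modes.
    Returns ``{site_label: {species: state}}``.
    """
    if mode not in ("binary", "residue"):
        raise ValueError(f"unknown mode {mode!r}")
    anaerobic: dict[str, str] = {}
    if mode == "binary":
        if panel is None:
            panel = default_panel()
        for marker in panel:
            for site in marker.sites:
                anaerobic[site_label(marker.marker_id, site.position)] = site.anaerobic_residue
        missing_sites = [s for s in matrix.sites if s not in anaerobic]
        if missing_sites:
            raise ValueError(f"matrix sites not in panel: {missing_sites}")
    out: dict[str, dict[str, str]] = {}
    for j, label in enumerate(matrix.sites):
        column: dict[str, str] = {}
        for i, name in enumerate(matrix.species):
            state = matrix.states[i][j]
            if state is MISSING:
                column[name] = UNKNOWN
            elif mode == "binary":
                column[name] = "1" if state == anaerobic[label] else "0"
            else:
                column[name] = str(state)
        out[label] = column
    return out


@dataclass(frozen=True)
class AncestralReconstruction:
    """Result of one Fitch pass over one character."""

    label: str
    min_changes: int
    root_states: frozenset[str]
    #: preferred state set per node id (id(node) keys are internal detail;
    #: use the accessors below)
    node_states: dict[int, frozenset[str]]
    tree: dendropy.Tree

    def states_of(self, node: dendropy.Node) -> frozenset[str]:
        return self.node_states[id(node)]

    def clade_states(self, tip_names: Sequence[str]) -> frozenset[str]:
        """Preferred state set of the most recent common ancestor of tips."""
        mrca = self.tree.mrca(taxon_labels=list(tip_names))
        if mrca is None:
            raise ValueError(f"no MRCA found for {list(tip_names)}")
        return self.states_of(mrca)


def fitch(
    tree: dendropy.Tree,
    character: Mapping[str, str],
    label: str = "",
    on_extra_species: str = "warn",
) -> AncestralReconstruction:
    """Small-parsimony reconstruction of one character on a rooted tree.

    ``character`` maps tip names to single-state strings or ``?``.  Tips
    absent from the mapping are treated as ``?``; species in the mapping
    but absent from the tree are dropped with a warning (or raise, with
    ``on_extra_species='error'``).  ``min_changes`` is the number of
    union operations in the bottom-up pass, i.e. the parsimony length.
    """
    tip_names = {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}
    extra = sorted(set(character) - tip_names)
    if extra:
        if on_extra_species == "error":
            raise ValueError(f"species not in tree: {extra}")
        import logging

        logging.getLogger(__name__).warning(
            "character %s: species not in tree dropped: %s", label, extra
        )
    observed = {
        name: s for name, s in character.items() if name in tip_names and s != UNKNOWN
    }
    if len(observed) < 2:
        raise UninformativeCharacterError(
            f"character {label or '<unnamed>'}: fewer than two observed tip states"
        )
    alphabet = frozenset(observed.values())

    prelim: dict[int, frozenset[str]] = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label if node.taxon else None
            state = character.get(name, UNKNOWN)
            prelim[id(node)] = alphabet if state == UNKNOWN else frozenset({state})
        else:
            children = node.child_nodes()
            acc = prelim[id(children[0])]
            for child in children[1:]:
                inter = acc & prelim[id(child)]
                if inter:
                    acc = inter
                else:
                    acc = acc | prelim[id(child)]
                    changes += 1
            prelim[id(node)] = acc

    final: dict[int, frozenset[str]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            final[id(node)] = prelim[id(node)]
        else:
            inter = prelim[id(node)] & final[id(node.parent_node)]
            final[id(node)] = inter if inter else prelim[id(node)]

    root = tree.seed_node
    return AncestralReconstruction(
        label=label,
        min_changes=changes,
        root_states=final[id(root)],
        node_states=final,
        tree=tree,
    )


def reconstruct_all(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    panel: Sequence[MarkerDefinition] | None = None,
    mode: str = "binary",
    clade_tips: Sequence[str] | None = None,
    on_extra_species: str = "warn",
) -> tuple[list[AncestralReconstruction], pd.DataFrame]:
    """Fitch reconstruction per matrix site plus a summary table.

    The summary has one row per site: parsimony length, root state set,
    and (if ``clade_tips`` names a clade of interest) the preferred state
    set of that clade's most recent common ancestor.
    """
    characters = encode_characters(matrix, panel=panel, mode=mode)
    recons: list[AncestralReconstruction] = []
    rows = []
    for label, column in characters.items():
        recon = fitch(tree, column, label=label, on_extra_species=on_extra_species)
        recons.append(recon)
        row = {
            "site": label,
            "min_changes": recon.min_changes,
            "root_states": "|".join(sorted(recon.root_states)),
        }
        if clade_tips:
            row["clade_ancestor_states"] = "|".join(sorted(recon.clade_states(clade_tips)))
        rows.append(row)
    return recons, pd.DataFrame(rows)


def annotated_newick(recon: AncestralReconstruction) -> str:
    """Newick string with node-state comments from one reconstruction."""
    tree = recon.tree.clone(depth=1)
    # clone preserves structure; map states by postorder correspondence
    orig_nodes = list(recon.tree.postorder_node_iter())
    for node, orig in zip(tree.postorder_node_iter(), orig_nodes):
        states = "|".join(sorted(recon.node_states[id(orig)]))
        node.annotations.add_new("states", states)
    return tree.as_string(schema="newick", suppress_rooting=True,
                          suppress_annotations=False, unquoted_underscores=True).strip() + "\n"
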