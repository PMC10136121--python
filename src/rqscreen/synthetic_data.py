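"""Synthetic inputs for every pipeline stage.

Real marker screens run against downloaded proteomes or genome contigs;
for testing, this module emulates their statistical structure instead:
one homolog per marker with the diagnostic residues planted at the exact
reference-mapped positions, embedded among random decoy proteins, with
controlled background substitution and indel noise; nucleotide contigs
that hide a marker on either strand in any frame; and tree-structured
genotype evolution for ancestral-reconstruction benchmarks.

What it deliberately does *not* model: realistic substitution matrices,
rate heterogeneity, domain structure in decoys, or paralogy.  Everything
is deterministic under its seed — identical configuration gives
byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio.Data import CodonTable

from .align import reverse_complement
from .io import SequenceRecord, write_fasta
from .markers import CallState, MARKER_IDS, site_label

__all__ = [
    "Genotype",
    "SimConfig",
    "ProteomeTruth",
    "TreeSimResult",
    "AEROBIC_RESIDUES",
    "REFERENCE_LENGTHS",
    "make_reference_set",
    "make_proteome",
    "make_contig",
    "evolve_on_tree",
    "write_dataset",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Stand-in reference protein lengths (long enough to host each marker's
#: largest site position with realistic flank).
REFERENCE_LENGTHS = {"COQ2": 370, "MEV1": 260, "TDO2": 300, "ETFDH": 620}

#: Anaerobic (RQ-capable) residue per panel site.
ANAEROBIC_RESIDUES = {
    "COQ2:204": "L",
    "COQ2:243": "S",
    "MEV1:71": "G",
    "TDO2:133": "P",
    "ETFDH:437": "F",
}

#: The purely aerobic states (the human row of the published table),
#: used as default VARIANT residues.
AEROBIC_RESIDUES = {
    "COQ2:204": "F",
    "COQ2:243": "A",
    "MEV1:71": "I",
    "TDO2:133": "A",
    "ETFDH:437": "C",
}

PANEL_LABELS = tuple(ANAEROBIC_RESIDUES)


@dataclass(frozen=True)
class Genotype:
    """Intended state per panel site: the residue planted in the homolog.

    A site whose planted residue equals the anaerobic residue is an
    ANAEROBIC_MATCH; any other residue is a VARIANT.
    """

    planted: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted", dict(self.planted))
        if set(self.planted) != set(PANEL_LABELS):
            raise ValueError(f"genotype must cover sites {PANEL_LABELS}")

    def expected_states(self) -> dict[str, CallState]:
        return {
            label: (
                CallState.ANAEROBIC_MATCH
                if res == ANAEROBIC_RESIDUES[label]
                else CallState.VARIANT
            )
            for label, res in self.planted.items()
        }

    def bits(self) -> tuple[int, ...]:
        """1 per site in the anaerobic state, panel order."""
        return tuple(
            int(self.planted[l] == ANAEROBIC_RESIDUES[l]) for l in PANEL_LABELS
        )

    @classmethod
    def all_anaerobic(cls) -> "Genotype":
        return cls(dict(ANAEROBIC_RESIDUES))

    @classmethod
    def aerobic_like(cls) -> "Genotype":
        return cls(dict(AEROBIC_RESIDUES))

    @classmethod
    def hydra_like(cls) -> "Genotype":
        """Anaerobic at all sites except a variant A at COQ2:243."""
        planted = dict(ANAEROBIC_RESIDUES)
        planted["COQ2:243"] = "A"
        return cls(planted)

    @classmethod
    def from_bits(cls, bits: Sequence[int]) -> "Genotype":
        if len(bits) != len(PANEL_LABELS):
            raise ValueError(f"need {len(PANEL_LABELS)} bits")
        return cls(
            {
                l: (ANAEROBIC_RESIDUES[l] if b else AEROBIC_RESIDUES[l])
                for l, b in zip(PANEL_LABELS, bits)
            }
        )

    def flipped(self, label: str) -> "Genotype":
        planted = dict(self.planted)
        planted[label] = (
            AEROBIC_RESIDUES[label]
            if planted[label] == ANAEROBIC_RESIDUES[label]
            else ANAEROBIC_RESIDUES[label]
        )
        return Genotype(planted)


@dataclass(frozen=True)
class SimConfig:
    """Noise and decoy settings for proteome generation.

    ``substitution_rate`` and ``indel_rate`` are per-position
    probabilities applied to the homolog outside the protected windows;
    ``protect_window`` shields +/- that many columns around each
    diagnostic site from all noise (set it to 0 to exercise
    position-mapping failure modes).
    """

    seed: int = 0
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    indel_mean_length: float = 2.0
    n_decoys: int = 20
    decoy_length_range: tuple[int, int] = (80, 600)
    protect_window: int = 2

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")


def _random_protein(rng: np.random.Generator, length: int, freqs=None) -> str:
    letters = rng.choice(list(_AA20), size=length, p=freqs)
    return "".join(letters)


def make_reference_set(seed: int = 0) -> dict[str, str]:
    """Random stand-in reference proteins with the panel residues planted.

    One protein per marker, at the default lengths, with each site's
    anaerobic residue at its exact 1-based reference position.  Fully
    deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    refs: dict[str, str] = {}
    for mid in MARKER_IDS:
        seq = list(_random_protein(rng, REFERENCE_LENGTHS[mid]))
        for label, residue in ANAEROBIC_RESIDUES.items():
            marker, pos = label.split(":")
            if marker == mid:
                seq[int(pos) - 1] = residue
        refs[mid] = "".join(seq)
    return refs


def _background_freqs(references: Mapping[str, str]) -> np.ndarray:
    pool = "".join(references.values())
    counts = np.array([pool.count(a) for a in _AA20], dtype=float)
    return counts / counts.sum()


def _site_positions(marker_id: str) -> list[int]:
    return [
        int(label.split(":")[1])
        for label in PANEL_LABELS
        if label.startswith(marker_id + ":")
    ]


def _mutate_homolog(
    ref: str,
    marker_id: str,
    genotype: Genotype,
    config: SimConfig,
    rng: np.random.Generator,
) -> str:
    """Plant genotype residues, then add noise outside protected windows."""
    chars = list(ref)
    positions = _site_positions(marker_id)
    for pos in positions:
        chars[pos - 1] = genotype.planted[site_label(marker_id, pos)]
    protected = set()
    for pos in positions:
        lo = max(0, pos - 1 - config.protect_window)
        hi = min(len(chars) - 1, pos - 1 + config.protect_window)
        protected.update(range(lo, hi + 1))

    if config.substitution_rate > 0:
        for i in range(len(chars)):
            if i not in protected and rng.random() < config.substitution_rate:
                alternatives = _AA20.replace(chars[i], "")
                chars[i] = alternatives[rng.integers(len(alternatives))]

    if config.indel_rate == 0:
        return "".join(chars)

    p_geom = min(1.0, 1.0 / max(config.indel_mean_length, 1.0))
    out: list[str] = []
    i = 0
    while i < len(chars):
        if i not in protected and rng.random() < config.indel_rate:
            length = int(rng.geometric(p_geom))
            if rng.random() < 0.5:  # deletion, never consuming protected columns
                taken = 0
                while taken < length and i < len(chars) and i not in protected:
                    i += 1
                    taken += 1
                continue
            out.extend(_random_protein(rng, length))
        out.append(chars[i])
        i += 1
    return "".join(out)


@dataclass(frozen=True)
class ProteomeTruth:
    """What was planted: homolog record ids and intended site states."""

    genotype: Genotype
    homolog_ids: dict[str, str]
    expected_states: dict[str, CallState] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for label, state in self.expected_states.items():
            marker = label.split(":")[0]
            rows.append(
                {
                    "site": label,
                    "planted_residue": self.genotype.planted[label],
                    "expected_state": state.value,
                    "homolog_id": self.homolog_ids[marker],
                }
            )
        return rows


def make_proteome(
    genotype: Genotype,
    config: SimConfig,
    references: Mapping[str, str] | None = None,
) -> tuple[list[SequenceRecord], ProteomeTruth]:
    """One mutated homolog per marker shuffled among random decoys.

    Decoy proteins are i.i.d. draws from the background amino-acid
    frequency of the reference set; the truth table records which record
    hosts each marker and the planted state per site.
    """
    if references is None:
        references = make_reference_set(config.seed)
    rng = np.random.default_rng(config.seed)
    freqs = _background_freqs(references)

    homologs = {
        mid: _mutate_homolog(references[mid], mid, genotype, config, rng)
        for mid in MARKER_IDS
    }
    lo, hi = config.decoy_length_range
    decoys = [
        _random_protein(rng, int(rng.integers(lo, hi + 1)), freqs)
        for _ in range(config.n_decoys)
    ]
    sequences = [("homolog", mid, seq) for mid, seq in homologs.items()]
    sequences += [("decoy", "", seq) for seq in decoys]
    order = rng.permutation(len(sequences))
    records: list[SequenceRecord] = []
    homolog_ids: dict[str, str] = {}
    for rank, idx in enumerate(order):
        kind, mid, seq = sequences[idx]
        rid = f"prot_{rank:05d}"
        if kind == "homolog":
            homolog_ids[mid] = rid
        records.append(SequenceRecord(id=rid, sequence=seq))
    truth = ProteomeTruth(
        genotype=genotype,
        homolog_ids=homolog_ids,
        expected_states=genotype.expected_states(),
    )
    return records, truth


_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()


def make_contig(
    protein: SequenceRecord,
    strand: str = "+",
    frame_offset: int = 0,
    seed: int = 0,
    flank_range: tuple[int, int] = (12, 60),
) -> SequenceRecord:
    """Reverse-translate a protein into a contig on a chosen strand/frame.

    Codons are drawn uniformly from the synonymous set (standard code);
    random flanks place the coding start at ``frame_offset`` (0/1/2) on
    the requested strand, so six-frame translation recovers the protein
    in exactly one frame.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    rng = np.random.default_rng(seed)
    coding = "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))]
        for aa in protein.sequence
    )
    lo, hi = flank_range
    flank5_len = int(rng.integers(lo, hi + 1))
    flank5_len += (frame_offset - flank5_len) % 3
    flank3_len = int(rng.integers(lo, hi + 1))
    nts = "ACGT"
    flank5 = "".join(nts[i] for i in rng.integers(4, size=flank5_len))
    flank3 = "".join(nts[i] for i in rng.integers(4, size=flank3_len))
    as_read = flank5 + coding + flank3
    seq = as_read if strand == "+" else reverse_complement(as_read)
    return SequenceRecord(
        id=f"{protein.id}_contig",
        sequence=seq,
        description=f"synthetic contig strand={strand} frame_offset={frame_offset}",
    )


@dataclass(frozen=True)
class TreeSimResult:
    """Tree-evolved genotypes: tips, internals, and materialized proteomes."""

    tree: dendropy.Tree
    root_genotype: Genotype
    node_genotypes: dict[str, Genotype]  # keyed by tip/internal node label
    tip_genotypes: dict[str, Genotype]
    tip_proteomes: dict[str, tuple[list[SequenceRecord], ProteomeTruth]]

    def tip_characters(self, label: str) -> dict[str, str]:
        """Binary ('1'/'0') tip states for one panel site."""
        idx = PANEL_LABELS.index(label)
        return {
            name: str(g.bits()[idx]) for name, g in self.tip_genotypes.items()
        }


def evolve_on_tree(
    tree: dendropy.Tree,
    root_genotype: Genotype,
    flip_probability: float,
    config: SimConfig,
    references: Mapping[str, str] | None = None,
    materialize_proteomes: bool = True,
) -> TreeSimResult:
    """Evolve panel genotypes along a tree and materialize tip proteomes.

    Each site flips between its anaerobic and variant state independently
    on every branch with ``flip_probability``.  Internal nodes without
    labels are named ``N0, N1, ...`` in preorder so the truth table can
    address them.
    """
    if not 0.0 <= flip_probability < 1.0:
        raise ValueError(f"flip_probability must be in [0, 1), got {flip_probability}")
    if references is None:
        references = make_reference_set(config.seed)
    rng = np.random.default_rng(config.seed)
    genotypes: dict[int, Genotype] = {}
    node_genotypes: dict[str, Genotype] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            g = root_genotype
        else:
            g = genotypes[id(node.parent_node)]
            for label in PANEL_LABELS:
                if rng.random() < flip_probability:
                    g = g.flipped(label)
        genotypes[id(node)] = g
        if node.is_leaf() and node.taxon is not None:
            name = node.taxon.label
        else:
            if node.label is None:
                node.label = f"N{counter}"
                counter += 1
            name = node.label
        node_genotypes[name] = g

    tip_genotypes = {
        leaf.taxon.label: genotypes[id(leaf)]
        for leaf in tree.leaf_node_iter()
        if leaf.taxon is not None
    }
    tip_proteomes: dict[str, tuple[list[SequenceRecord], ProteomeTruth]] = {}
    if materialize_proteomes:
        for name in sorted(tip_genotypes):
            tip_seed = int(rng.integers(2**31))
            tip_config = SimConfig(
                seed=tip_seed,
                substitution_rate=config.substitution_rate,
                indel_rate=config.indel_rate,
                indel_mean_length=config.indel_mean_length,
                n_decoys=config.n_decoys,
                decoy_length_range=config.decoy_length_range,
                protect_window=config.protect_window,
            )
            tip_proteomes[name] = make_proteome(
                tip_genotypes[name], tip_config, references
            )
    return TreeSimResult(
        tree=tree,
        root_genotype=root_genotype,
        node_genotypes=node_genotypes,
        tip_genotypes=tip_genotypes,
        tip_proteomes=tip_proteomes,
    )


def write_dataset(
    outdir,
    genotype: Genotype,
    config: SimConfig,
    references: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Write a simulated proteome dataset: FASTA, truth TSV, config sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if references is None:
        references = make_reference_set(config.seed)
    records, truth = make_proteome(genotype, config, references)
    paths = {
        "proteome": str(outdir / "proteome.fasta"),
        "references": str(outdir / "references.fasta"),
        "truth": str(outdir / "truth.tsv"),
        "config": str(outdir / "config.json"),
    }
    write_fasta(records, paths["proteome"])
    write_fasta(
        [SequenceRecord(id=mid, sequence=references[mid]) for mid in MARKER_IDS],
        paths["references"],
    )
    rows = truth.to_rows()
    header = ["site", "planted_residue", "expected_state", "homolog_id"]
    with open(paths["truth"], "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[k]) for k in header) + "\n")
    sidecar = {"genotype": dict(genotype.planted), "config": asdict(config)}
    with open(paths["config"], "wt") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
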