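"""The rhodoquinone (RQ) marker panel and the residue-diagnostic screen.

Facultatively anaerobic mitochondria run a truncated electron transport
chain with fumarate as terminal acceptor, which requires rhodoquinone in
place of ubiquinone.  Four enzymes carry diagnostic residues that
distinguish the RQ-capable form from the purely aerobic one, all given in
the coordinates of the Caenorhabditis elegans reference proteins:

====== ============== ===================== ==========================
marker accession       diagnostic site(s)    role
====== ============== ===================== ==========================
COQ2   NP_871684.1    L204, S243            quinone biosynthesis;
                                            alternatively spliced exon
MEV1   NP_001366681.1 G71                   Complex II subunit, quinone
                                            binding pocket
TDO2   NP_498284.1    P133                  RQ synthesis pathway
                                            (PLD loop)
ETFDH  NP_001379625.1 F437                  electron transfer
                                            flavoprotein dehydrogenase,
                                            RQ docking site
====== ============== ===================== ==========================

The screen finds the best homolog of each marker in a proteome (or in
the six-frame translation of nucleotide contigs), maps each diagnostic
site through the alignment, calls the observed residue, and classifies
the species from the five calls.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._sentinels import GAP, MISSING
from .align import (
    AlignParams,
    Alignment,
    DEFAULT_PARAMS,
    local_align,
    map_positions,
    six_frame_translate,
)
from .errors import PanelError
from .io import CharacterMatrix, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosticSite",
    "MarkerDefinition",
    "HomologHit",
    "ResidueCall",
    "CallState",
    "Classification",
    "SpeciesProfile",
    "Thresholds",
    "default_panel",
    "panel_site_labels",
    "site_label",
    "find_homolog",
    "call_sites",
    "classify_species",
    "screen_proteome",
    "classify_matrix",
    "MatrixSummary",
    "MARKER_IDS",
    "REFERENCE_ACCESSIONS",
]

MARKER_IDS = ("COQ2", "MEV1", "TDO2", "ETFDH")

REFERENCE_ACCESSIONS = {
    "COQ2": "NP_871684.1",
    "MEV1": "NP_001366681.1",
    "TDO2": "NP_498284.1",
    "ETFDH": "NP_001379625.1",
}

# (position, anaerobic residue, note) per marker; positions are 1-based in
# the C. elegans reference proteins.
_PANEL_SITES = {
    "COQ2": (
        (204, "L", "close to the substrate in the active site"),
        (243, "S", "close to the substrate in the active site"),
    ),
    "MEV1": ((71, "G", "near the rhodoquinone ring's binding site"),),
    "TDO2": ((133, "P", "part of the PLD loop required for activity"),),
    "ETFDH": ((437, "F", "near the quinone binding site"),),
}

_EXPECTED_SITE_COUNTS = {"COQ2": 2, "MEV1": 1, "TDO2": 1, "ETFDH": 1}

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class DiagnosticSite:
    """One diagnostic residue position in a reference protein."""

    position: int
    anaerobic_residue: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise PanelError(f"site position must be >= 1, got {self.position}")
        if self.anaerobic_residue not in _VALID_AA:
            raise PanelError(
                f"invalid anaerobic residue {self.anaerobic_residue!r}"
            )


@dataclass(frozen=True)
class MarkerDefinition:
    marker_id: str
    sites: tuple[DiagnosticSite, ...]
    reference_species: str = "Caenorhabditis elegans"
    reference_accession: str = ""
    reference_sequence: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        if not self.sites:
            raise PanelError(f"marker {self.marker_id}: no diagnostic sites")
        expected = _EXPECTED_SITE_COUNTS.get(self.marker_id)
        if expected is not None and len(self.sites) != expected:
            raise PanelError(
                f"marker {self.marker_id}: expected {expected} site(s), "
                f"got {len(self.sites)}"
            )
        if self.reference_sequence is not None:
            max_pos = max(s.position for s in self.sites)
            if len(self.reference_sequence) < max_pos:
                raise PanelError(
                    f"marker {self.marker_id}: reference sequence length "
                    f"{len(self.reference_sequence)} is shorter than site "
                    f"position {max_pos}"
                )

    @property
    def site_labels(self) -> tuple[str, ...]:
        return tuple(site_label(self.marker_id, s.position) for s in self.sites)


def site_label(marker_id: str, position: int) -> str:
    return f"{marker_id}:{position}"


def default_panel(
    reference_sequences: Mapping[str, str] | None = None,
) -> list[MarkerDefinition]:
    """The four-marker RQ panel: COQ2 {204:L, 243:S}, MEV1 {71:G},
    TDO2 {133:P}, ETFDH {437:F}.

    ``reference_sequences`` optionally attaches a protein per marker id
    (real accession downloads or synthetic stand-ins); without sequences
    the panel is still usable against a printed character matrix.
    """
    panel = []
    for mid in MARKER_IDS:
        seq = None if reference_sequences is None else reference_sequences.get(mid)
        panel.append(
            MarkerDefinition(
                marker_id=mid,
                sites=tuple(DiagnosticSite(*s) for s in _PANEL_SITES[mid]),
                reference_accession=REFERENCE_ACCESSIONS[mid],
                reference_sequence=seq,
            )
        )
    return panel


def panel_site_labels(panel: Sequence[MarkerDefinition]) -> tuple[str, ...]:
    labels: list[str] = []
    for marker in panel:
        labels.extend(marker.site_labels)
    return tuple(labels)


@dataclass(frozen=True)
class Thresholds:
    """Homolog acceptance thresholds (fractions of 1)."""

    min_identity: float = 0.30
    min_coverage: float = 0.60


@dataclass(frozen=True)
class HomologHit:
    marker_id: str
    target_id: str
    target_sequence: str = field(repr=False, default="")
    alignment: Alignment = field(repr=False, default=None)
    identity_fraction: float = 0.0
    reference_coverage_fraction: float = 0.0


class CallState(enum.Enum):
    ANAEROBIC_MATCH = "ANAEROBIC_MATCH"
    VARIANT = "VARIANT"
    MISSING = "MISSING"


class Classification(enum.Enum):
    FULL_SIGNATURE = "FULL_SIGNATURE"
    PARTIAL_SIGNATURE = "PARTIAL_SIGNATURE"
    NO_SIGNATURE = "NO_SIGNATURE"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


@dataclass(frozen=True)
class ResidueCall:
    marker_id: str
    site: DiagnosticSite
    observed: object  # one-letter residue or MISSING
    state: CallState

    @property
    def label(self) -> str:
        return site_label(self.marker_id, self.site.position)


@dataclass(frozen=True)
class SpeciesProfile:
    species: str
    calls: tuple[ResidueCall, ...]
    classification: Classification
    n_match: int
    n_variant: int
    n_missing: int

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "classification": self.classification.value,
            "counts": {
                "match": self.n_match,
                "variant": self.n_variant,
                "missing": self.n_missing,
            },
            "calls": [
                {
                    "site": c.label,
                    "anaerobic_residue": c.site.anaerobic_residue,
                    "observed": None if c.observed is MISSING else c.observed,
                    "state": c.state.value,
                }
                for c in self.calls
            ],
        }


def find_homolog(
    marker: MarkerDefinition,
    proteome: Sequence[SequenceRecord],
    thresholds: Thresholds = Thresholds(),
    params: AlignParams = DEFAULT_PARAMS,
) -> HomologHit | None:
    """Best local alignment of the marker reference across a proteome.

    Returns the best-scoring hit only if it clears both the identity and
    reference-coverage thresholds; score ties are broken by longer
    reference coverage, then by lexicographic target id.
    """
    if marker.reference_sequence is None:
        raise PanelError(f"marker {marker.marker_id} has no reference sequence")
    if not proteome:
        logger.warning("find_homolog(%s): empty proteome", marker.marker_id)
        return None
    ref = marker.reference_sequence
    best: tuple[int, float, str] | None = None
    best_hit: HomologHit | None = None
    for record in sorted(proteome, key=lambda r: r.id):
        aln = local_align(ref, record.sequence, params)
        if aln.ref_span is None:
            continue
        coverage = (aln.ref_span[1] - aln.ref_span[0] + 1) / len(ref)
        # sort key: higher score, then higher coverage, then earlier id
        key = (-aln.score, -coverage, record.id)
        if best is None or key < best:
            best = key
            best_hit = HomologHit(
                marker_id=marker.marker_id,
                target_id=record.id,
                target_sequence=record.sequence,
                alignment=aln,
                identity_fraction=aln.identity_fraction(),
                reference_coverage_fraction=coverage,
            )
    if best_hit is None:
        return None
    if (
        best_hit.identity_fraction < thresholds.min_identity
        or best_hit.reference_coverage_fraction < thresholds.min_coverage
    ):
        logger.info(
            "find_homolog(%s): best hit %s rejected (identity %.3f, coverage %.3f)",
            marker.marker_id,
            best_hit.target_id,
            best_hit.identity_fraction,
            best_hit.reference_coverage_fraction,
        )
        return None
    return best_hit


def call_sites(marker: MarkerDefinition, hit: HomologHit | None) -> list[ResidueCall]:
    """Read each diagnostic site of ``marker`` off a homolog hit.

    No hit, a site outside the aligned reference span, or a site mapped
    into a deletion all yield MISSING; otherwise the target residue is
    compared to the site's anaerobic residue.
    """
    calls: list[ResidueCall] = []
    posmap = map_positions(hit.alignment) if hit is not None else None
    for site in marker.sites:
        observed: object = MISSING
        if hit is not None and site.position in posmap:
            target_pos = posmap[site.position]
            if target_pos is not GAP:
                observed = hit.target_sequence[target_pos - 1]
        if observed is MISSING:
            state = CallState.MISSING
        elif observed == site.anaerobic_residue:
            state = CallState.ANAEROBIC_MATCH
        else:
            state = CallState.VARIANT
        calls.append(
            ResidueCall(marker_id=marker.marker_id, site=site, observed=observed, state=state)
        )
    return calls


def classify_species(species: str, calls: Sequence[ResidueCall]) -> SpeciesProfile:
    """Classify a species from its five panel calls.

    FULL_SIGNATURE: all five sites match the anaerobic residues.
    NO_SIGNATURE: zero matches with all five sites observed.
    INSUFFICIENT_DATA: zero matches and at least one site unobserved.
    PARTIAL_SIGNATURE: anything else.  A pure function of the multiset
    of call states.
    """
    n_panel = sum(_EXPECTED_SITE_COUNTS.values())
    if len(calls) != n_panel:
        raise ValueError(f"expected {n_panel} calls, got {len(calls)}")
    n_match = sum(c.state is CallState.ANAEROBIC_MATCH for c in calls)
    n_variant = sum(c.state is CallState.VARIANT for c in calls)
    n_missing = sum(c.state is CallState.MISSING for c in calls)
    if n_match == n_panel:
        cls = Classification.FULL_SIGNATURE
    elif n_match == 0 and n_missing == 0:
        cls = Classification.NO_SIGNATURE
    elif n_match == 0:
        cls = Classification.INSUFFICIENT_DATA
    else:
        cls = Classification.PARTIAL_SIGNATURE
    return SpeciesProfile(
        species=species,
        calls=tuple(calls),
        classification=cls,
        n_match=n_match,
        n_variant=n_variant,
        n_missing=n_missing,
    )


@dataclass(frozen=True)
class ScreenResult:
    profile: SpeciesProfile
    matrix_row: CharacterMatrix
    hits: dict[str, HomologHit | None]

    def display_row(self) -> str:
        """Row in the printed-table style, e.g. ``L;S G P F``."""
        states = {c.label: c.observed for c in self.profile.calls}
        labels = [c.label for c in self.profile.calls]

        def fmt(label: str) -> str:
            s = states[label]
            return "-" if s is MISSING else str(s)

        coq2 = ";".join(fmt(l) for l in labels[:2])
        rest = " ".join(fmt(l) for l in labels[2:])
        return f"{coq2} {rest}"


#: Minimum peptide-segment length considered when screening nucleotide
#: contigs through six-frame translation.
MIN_SEGMENT_LENGTH = 30


def _translated_proteome(contigs: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    candidates: list[SequenceRecord] = []
    for contig in contigs:
        for seg in six_frame_translate(contig.sequence, min_length=MIN_SEGMENT_LENGTH):
            candidates.append(
                SequenceRecord(
                    id=f"{contig.id}|frame{seg.frame:+d}|{seg.nt_start}",
                    sequence=seg.peptide,
                    description=f"six-frame segment of {contig.id}",
                )
            )
    return candidates


def screen_proteome(
    panel: Sequence[MarkerDefinition],
    records: Sequence[SequenceRecord],
    species: str,
    thresholds: Thresholds = Thresholds(),
    params: AlignParams = DEFAULT_PARAMS,
    seqtype: str = "protein",
) -> ScreenResult:
    """End-to-end screen of one species' sequences against the panel.

    ``seqtype='nucleotide'`` routes contigs through six-frame translation
    and screens every stop-free peptide segment of length >=
    ``MIN_SEGMENT_LENGTH`` exactly like proteins.
    """
    if seqtype == "nucleotide":
        candidates = _translated_proteome(records)
    elif seqtype == "protein":
        candidates = list(records)
    else:
        raise ValueError(f"unknown seqtype {seqtype!r}")
    calls: list[ResidueCall] = []
    hits: dict[str, HomologHit | None] = {}
    for marker in panel:
        hit = find_homolog(marker, candidates, thresholds, params)
        hits[marker.marker_id] = hit
        calls.extend(call_sites(marker, hit))
    profile = classify_species(species, calls)
    labels = panel_site_labels(panel)
    row = CharacterMatrix(
        species=(species,),
        sites=labels,
        states=(tuple(c.observed if c.observed is not MISSING else MISSING for c in profile.calls),),
    )
    return ScreenResult(profile=profile, matrix_row=row, hits=hits)


@dataclass(frozen=True)
class MatrixSummary:
    n_species: int
    classification_counts: dict[str, int]
    per_site_match_counts: dict[str, int]
    full_signature_species: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "classification_counts": dict(self.classification_counts),
            "per_site_match_counts": dict(self.per_site_match_counts),
            "full_signature_species": list(self.full_signature_species),
        }


def _calls_from_states(
    panel: Sequence[MarkerDefinition], states: Mapping[str, object]
) -> list[ResidueCall]:
    calls = []
    for marker in panel:
        for site in marker.sites:
            observed = states[site_label(marker.marker_id, site.position)]
            if observed is MISSING:
                state = CallState.MISSING
            elif observed == site.anaerobic_residue:
                state = CallState.ANAEROBIC_MATCH
            else:
                state = CallState.VARIANT
            calls.append(ResidueCall(marker.marker_id, site, observed, state))
    return calls


def classify_matrix(
    matrix: CharacterMatrix, panel: Sequence[MarkerDefinition] | None = None
) -> tuple[list[SpeciesProfile], MatrixSummary]:
    """Apply the call/classify logic directly to a printed state matrix."""
    if panel is None:
        panel = default_panel()
    labels = panel_site_labels(panel)
    if set(matrix.sites) != set(labels):
        raise ValueError(
            f"matrix sites {sorted(matrix.sites)} do not match panel sites "
            f"{sorted(labels)}"
        )
    profiles: list[SpeciesProfile] = []
    for name in matrix.species:
        calls = _calls_from_states(panel, matrix.row(name))
        profiles.append(classify_species(name, calls))
    cls_counts = {c.value: 0 for c in Classification}
    site_matches = {label: 0 for label in labels}
    for p in profiles:
        cls_counts[p.classification.value] += 1
        for c in p.calls:
            if c.state is CallState.ANAEROBIC_MATCH:
                site_matches[c.label] += 1
    summary = MatrixSummary(
        n_species=len(profiles),
        classification_counts=cls_counts,
        per_site_match_counts=site_matches,
        full_signature_species=tuple(
            p.species for p in profiles if p.classification is Classification.FULL_SIGNATURE
        ),
    )
    return profiles, summary
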