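"""Marker panel, homolog search, residue calling, and classification."""

import numpy as np
import pytest

from rqscreen.align import Alignment, score_alignment
from rqscreen.errors import PanelError
from rqscreen.io import MISSING, CharacterMatrix, SequenceRecord
from rqscreen.datasets import table1_cnidarians
from rqscreen.markers import (
    CallState,
    Classification,
    DiagnosticSite,
    HomologHit,
    MarkerDefinition,
    ResidueCall,
    Thresholds,
    call_sites,
    classify_matrix,
    classify_species,
    default_panel,
    find_homolog,
    panel_site_labels,
    screen_proteome,
)
from rqscreen.synthetic_data import Genotype, SimConfig, make_contig, make_proteome

from oracles import random_protein


class TestPanel:
    def test_default_panel_sites(self):
        panel = {m.marker_id: m for m in default_panel()}
        assert [(s.position, s.anaerobic_residue) for s in panel["COQ2"].sites] == [
            (204, "L"),
            (243, "S"),
        ]
        assert [(s.position, s.anaerobic_residue) for s in panel["MEV1"].sites] == [(71, "G")]
        assert [(s.position, s.anaerobic_residue) for s in panel["TDO2"].sites] == [(133, "P")]
        assert [(s.position, s.anaerobic_residue) for s in panel["ETFDH"].sites] == [(437, "F")]
        assert len(panel_site_labels(default_panel())) == 5

    def test_accessions(self):
        panel = {m.marker_id: m for m in default_panel()}
        assert panel["COQ2"].reference_accession == "NP_871684.1"
        assert panel["ETFDH"].reference_accession == "NP_001379625.1"

    def test_short_reference_sequence_rejected(self):
        with pytest.raises(PanelError, match="shorter than site position 243"):
            default_panel({"COQ2": "M" * 100})

    def test_wrong_site_count_rejected(self):
        with pytest.raises(PanelError, match="expected 2"):
            MarkerDefinition(marker_id="COQ2", sites=(DiagnosticSite(204, "L"),))


class TestFindHomolog:
    def test_exact_copy_dominates_decoys(self, panel, references):
        rng = np.random.default_rng(0)
        marker = panel[0]
        proteome = [SequenceRecord(id=f"d{i}", sequence=random_protein(rng, 300)) for i in range(20)]
        proteome.append(SequenceRecord(id="copy", sequence=references["COQ2"]))
        hit = find_homolog(marker, proteome)
        assert hit.target_id == "copy"
        assert hit.identity_fraction == 1.0
        assert hit.reference_coverage_fraction == 1.0

    def test_decoys_only_returns_none(self, panel):
        rng = np.random.default_rng(1)
        proteome = [SequenceRecord(id=f"d{i}", sequence=random_protein(rng, 250)) for i in range(10)]
        assert find_homolog(panel[0], proteome) is None

    def test_empty_proteome_returns_none(self, panel, caplog):
        assert find_homolog(panel[0], []) is None

    def test_diverged_homolog_is_best_hit_across_replicates(self, panel, references):
        # ~85% identity homolog among decoys must win the search every time
        marker = {m.marker_id: m for m in panel}["MEV1"]
        for rep in range(50):
            cfg = SimConfig(seed=900 + rep, substitution_rate=0.15, n_decoys=20)
            records, truth = make_proteome(Genotype.all_anaerobic(), cfg, references)
            hit = find_homolog(marker, records)
            assert hit is not None
            assert hit.target_id == truth.homolog_ids["MEV1"]


class TestCallSites:
    def test_exact_reference_matches_all_sites(self, panel, references):
        for marker in panel:
            proteome = [SequenceRecord(id="self", sequence=references[marker.marker_id])]
            calls = call_sites(marker, find_homolog(marker, proteome))
            assert all(c.state is CallState.ANAEROBIC_MATCH for c in calls)

    def test_no_hit_gives_missing(self, panel):
        calls = call_sites(panel[0], None)
        assert all(c.state is CallState.MISSING and c.observed is MISSING for c in calls)

    def test_variant_residue_called(self):
        # Hydra-like COQ2: L at 204-equivalent, A (not S) at 243-equivalent
        marker = MarkerDefinition(
            marker_id="COQ2",
            sites=(DiagnosticSite(2, "L"), DiagnosticSite(4, "S")),
            reference_sequence="MLKSV",
        )
        target = "MLKAV"
        aln = Alignment("MLKSV", target, score=score_alignment("MLKSV", target),
                        mode="local", ref_span=(1, 5), target_span=(1, 5))
        hit = HomologHit("COQ2", "t", target, aln, 0.8, 1.0)
        states = [c.state for c in call_sites(marker, hit)]
        assert states == [CallState.ANAEROBIC_MATCH, CallState.VARIANT]

    def test_deleted_site_column_is_missing(self):
        marker = MarkerDefinition(
            marker_id="MEV1", sites=(DiagnosticSite(3, "G"),), reference_sequence="MKGLW"
        )
        aln = Alignment("MKGLW", "MK-LW", score=score_alignment("MKGLW", "MK-LW"),
                        mode="global", ref_span=(1, 5), target_span=(1, 4))
        hit = HomologHit("MEV1", "t", "MKLW", aln, 0.8, 1.0)
        (call,) = call_sites(marker, hit)
        assert call.state is CallState.MISSING


class TestClassify:
    def _calls(self, states):
        panel = default_panel()
        calls = []
        i = 0
        for marker in panel:
            for site in marker.sites:
                s = states[i]
                observed = site.anaerobic_residue if s == "M" else MISSING if s == "?" else "Q"
                state = (
                    CallState.ANAEROBIC_MATCH
                    if s == "M"
                    else CallState.MISSING
                    if s == "?"
                    else CallState.VARIANT
                )
                calls.append(ResidueCall(marker.marker_id, site, observed, state))
                i += 1
        return calls

    @pytest.mark.parametrize(
        "states,expected,counts",
        [
            ("MMMMM", Classification.FULL_SIGNATURE, (5, 0, 0)),
            ("VVVVV", Classification.NO_SIGNATURE, (0, 5, 0)),
            ("?????", Classification.INSUFFICIENT_DATA, (0, 0, 5)),
            ("MVMVM", Classification.PARTIAL_SIGNATURE, (3, 2, 0)),
            ("V?V?V", Classification.INSUFFICIENT_DATA, (0, 3, 2)),
            ("M????", Classification.PARTIAL_SIGNATURE, (1, 0, 4)),
        ],
    )
    def test_classification_rules(self, states, expected, counts):
        profile = classify_species("x", self._calls(states))
        assert profile.classification is expected
        assert (profile.n_match, profile.n_variant, profile.n_missing) == counts

    def test_order_invariance(self):
        calls = self._calls("MV?VM")
        base = classify_species("x", calls)
        rng = np.random.default_rng(2)
        for _ in range(5):
            shuffled = [calls[i] for i in rng.permutation(5)]
            again = classify_species("x", shuffled)
            assert again.classification is base.classification
            assert (again.n_match, again.n_variant, again.n_missing) == (
                base.n_match, base.n_variant, base.n_missing,
            )

    def test_wrong_call_count_rejected(self):
        with pytest.raises(ValueError, match="expected 5 calls"):
            classify_species("x", self._calls("MMMMM")[:4])


class TestScreenProteome:
    def test_anaerobic_proteome_full_signature(self, panel, references):
        records, _ = make_proteome(Genotype.all_anaerobic(), SimConfig(seed=3), references)
        result = screen_proteome(panel, records, "synthetic anaerobe")
        assert result.profile.classification is Classification.FULL_SIGNATURE
        assert result.display_row() == "L;S G P F"

    def test_aerobic_proteome_no_signature(self, panel, references):
        records, _ = make_proteome(Genotype.aerobic_like(), SimConfig(seed=4), references)
        result = screen_proteome(panel, records, "synthetic aerobe")
        assert result.profile.classification is Classification.NO_SIGNATURE
        assert result.display_row() == "F;A I A C"

    def test_reverse_strand_contigs_match_protein_route(self, panel, references):
        records, _ = make_proteome(Genotype.hydra_like(), SimConfig(seed=5), references)
        protein_route = screen_proteome(panel, records, "sp")
        contigs = [
            make_contig(rec, strand="-", frame_offset=1, seed=50 + i)
            for i, rec in enumerate(records)
        ]
        nt_route = screen_proteome(panel, contigs, "sp", seqtype="nucleotide")
        assert [c.state for c in nt_route.profile.calls] == [
            c.state for c in protein_route.profile.calls
        ]
        assert nt_route.profile.classification is protein_route.profile.classification

    def test_matrix_row_mirrors_calls(self, panel, references):
        records, _ = make_proteome(Genotype.hydra_like(), SimConfig(seed=6), references)
        result = screen_proteome(panel, records, "sp")
        assert result.matrix_row.species == ("sp",)
        assert result.matrix_row.row("sp")["COQ2:243"] == "A"


class TestClassifyMatrix:
    def test_exactly_one_cnidarian_full_signature(self, table1):
        profiles, summary = classify_matrix(table1)
        cnidarians = set(table1_cnidarians(table1))
        full = [p.species for p in profiles
                if p.species in cnidarians
                and p.classification is Classification.FULL_SIGNATURE]
        assert full == ["Nematostella vectensis"]

    def test_all_cnidarians_match_etfdh_site(self, table1):
        profiles, _ = classify_matrix(table1)
        cnidarians = set(table1_cnidarians(table1))
        for p in profiles:
            if p.species not in cnidarians:
                continue
            etfdh = [c for c in p.calls if c.label == "ETFDH:437"]
            assert etfdh[0].state is CallState.ANAEROBIC_MATCH
            assert p.classification is not Classification.NO_SIGNATURE

    def test_empty_matrix(self):
        matrix = CharacterMatrix(
            species=(), sites=("COQ2:204", "COQ2:243", "MEV1:71", "TDO2:133", "ETFDH:437"),
            states=(),
        )
        profiles, summary = classify_matrix(matrix)
        assert profiles == []
        assert summary.n_species == 0
        assert sum(summary.classification_counts.values()) == 0

    def test_site_mismatch_rejected(self, table1):
        bad = CharacterMatrix(species=("x",), sites=("COQ2:1",), states=(("L",),))
        with pytest.raises(ValueError, match="do not match panel"):
            classify_matrix(bad)

    def test_summary_counts(self, table1):
        _, summary = classify_matrix(table1)
        assert summary.n_species == 18
        assert summary.per_site_match_counts["ETFDH:437"] == 17  # all but H. sapiens
        assert summary.classification_counts["INSUFFICIENT_DATA"] == 0
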