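"""Pairwise alignment, position mapping, and six-frame translation."""

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from hypothesis import given, strategies as st

from rqscreen.align import (
    AlignParams,
    Alignment,
    GAP,
    global_align,
    local_align,
    map_positions,
    score_alignment,
    six_frame_translate,
)
from rqscreen.errors import InvalidSequenceError
from rqscreen.synthetic_data import SimConfig, make_reference_set, _mutate_homolog, Genotype

from oracles import (
    brute_force_global,
    brute_force_local,
    brute_force_local_enum,
    random_protein,
)

PROTEIN = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


class TestGlobal:
    def test_identical_short_sequences(self):
        b62 = substitution_matrices.load("BLOSUM62")
        expected = int(b62["M", "M"] + b62["K", "K"] + b62["V", "V"])
        aln = global_align("MKV", "MKV")
        assert aln.score == expected == 14
        assert aln.aligned_ref == aln.aligned_target == "MKV"

    @given(PROTEIN)
    def test_self_alignment_has_no_gaps(self, seq):
        aln = global_align(seq, seq)
        assert aln.aligned_ref == aln.aligned_target == seq
        assert aln.score == score_alignment(seq, seq)

    @given(PROTEIN, PROTEIN)
    def test_score_recomputable_from_aligned_strings(self, a, b):
        aln = global_align(a, b)
        assert aln.aligned_ref.replace("-", "") == a
        assert aln.aligned_target.replace("-", "") == b
        assert score_alignment(aln.aligned_ref, aln.aligned_target) == aln.score

    def test_invalid_residue_names_symbol_and_position(self):
        with pytest.raises(InvalidSequenceError, match=r"'B' at position 3"):
            global_align("MKB", "MKV")


class TestLocal:
    def test_embedded_motif(self):
        aln = local_align("AAAMKVAAA", "MKV")
        assert aln.score == 14
        assert aln.target_span == (1, 3)
        assert aln.ref_span == (4, 6)
        assert aln.aligned_ref == "MKV"

    def test_no_positive_scoring_pair_gives_empty_alignment(self):
        aln = local_align("GGGG", "WW", AlignParams())
        # BLOSUM62 G/W = -2: nothing positive to seed a local alignment
        assert aln.score == 0 and aln.aligned_ref == "" and aln.ref_span is None

    @given(st.integers(0, 10_000))
    def test_local_score_recomputable(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, int(rng.integers(5, 30)))
        b = random_protein(rng, int(rng.integers(5, 30)))
        aln = local_align(a, b)
        if aln.ref_span is not None:
            assert score_alignment(aln.aligned_ref, aln.aligned_target) == aln.score
            i0, i1 = aln.ref_span
            assert aln.aligned_ref.replace("-", "") == a[i0 - 1 : i1]


class TestBruteForceOracle:
    """DP scores equal exhaustive enumeration over the alignment space."""

    def test_global_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = random_protein(rng, int(rng.integers(1, 9)))
            b = random_protein(rng, int(rng.integers(1, 9)))
            assert global_align(a, b).score == brute_force_global(a, b)

    def test_local_matches_exhaustive_search(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            a = random_protein(rng, int(rng.integers(1, 9)))
            b = random_protein(rng, int(rng.integers(1, 9)))
            assert local_align(a, b).score == brute_force_local(a, b)

    def test_local_oracles_agree_on_tiny_inputs(self):
        # the memoised search itself cross-checked against pure enumeration
        rng = np.random.default_rng(44)
        for _ in range(10):
            a = random_protein(rng, int(rng.integers(1, 5)))
            b = random_protein(rng, int(rng.integers(1, 5)))
            assert brute_force_local(a, b) == brute_force_local_enum(a, b)

    def test_scores_match_independent_aligner(self):
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(45)
        for _ in range(20):
            a = random_protein(rng, int(rng.integers(10, 60)))
            b = random_protein(rng, int(rng.integers(10, 60)))
            aligner.mode = "global"
            assert global_align(a, b).score == aligner.score(a, b)
            aligner.mode = "local"
            assert local_align(a, b).score == aligner.score(a, b)


class TestPositionMap:
    def test_identity_map_on_self_alignment(self):
        aln = global_align("MKVLW", "MKVLW")
        pm = map_positions(aln)
        assert dict(pm.items()) == {i: i for i in range(1, 6)}

    def test_deletion_maps_to_gap(self):
        aln = Alignment("MKV", "M-V", score=score_alignment("MKV", "M-V"),
                        mode="global", ref_span=(1, 3), target_span=(1, 2))
        pm = map_positions(aln)
        assert pm[1] == 1 and pm[2] is GAP and pm[3] == 2

    def test_mapped_positions_strictly_increasing(self):
        rng = np.random.default_rng(46)
        a = random_protein(rng, 50)
        b = random_protein(rng, 60)
        pm = map_positions(local_align(a, b))
        mapped = [v for _, v in sorted(pm.items()) if v is not GAP]
        assert mapped == sorted(set(mapped))


class TestPlantedResidueRecovery:
    """Diagnostic residues planted in a noisy homolog are read back through
    the alignment's position map."""

    @staticmethod
    def _recovery_rate(sub_rate, indel_rate, n_reps, seed0):
        refs = make_reference_set(seed=11)
        ref = refs["ETFDH"]
        ok = 0
        for rep in range(n_reps):
            cfg = SimConfig(seed=seed0 + rep, substitution_rate=sub_rate,
                            indel_rate=indel_rate)
            hom = _mutate_homolog(ref, "ETFDH", Genotype.all_anaerobic(), cfg,
                                  np.random.default_rng(seed0 + rep))
            pm = map_positions(local_align(ref, hom))
            pos = pm.get(437)
            if pos is not None and pos is not GAP and hom[pos - 1] == "F":
                ok += 1
        return ok / n_reps

    def test_substitution_only_noise_recovers_always(self):
        assert self._recovery_rate(0.02, 0.0, 50, seed0=100) == 1.0

    def test_low_indel_rate_recovers_at_least_95_percent(self):
        assert self._recovery_rate(0.0, 0.005, 50, seed0=200) >= 0.95


class TestSixFrame:
    @pytest.mark.parametrize(
        "seq,frame,expected",
        [
            ("ATGGCC", 1, ["MA"]),
            ("GGCCAT", -1, ["MA"]),
            ("ATGTAAATG", 1, ["M", "M"]),
        ],
    )
    def test_known_translations(self, seq, frame, expected):
        peptides = [s.peptide for s in six_frame_translate(seq) if s.frame == frame]
        assert peptides == expected

    def test_n_translates_to_x(self):
        segs = [s for s in six_frame_translate("ATGNCC") if s.frame == 1]
        assert segs[0].peptide == "MX"

    def test_invalid_nucleotide_rejected(self):
        with pytest.raises(InvalidSequenceError, match="'R' at position 3"):
            six_frame_translate("ACRT")

    @given(st.text(alphabet="ACGT", min_size=6, max_size=60))
    def test_reverse_frames_equal_forward_frames_of_revcomp(self, seq):
        from rqscreen.align import reverse_complement

        fwd = six_frame_translate(reverse_complement(seq))
        rev = six_frame_translate(seq)
        for k in (1, 2, 3):
            got = [s.peptide for s in rev if s.frame == -k]
            expected = [s.peptide for s in fwd if s.frame == k]
            assert got == expected
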