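import io

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given
from hypothesis import strategies as st

from thermoshift.errors import ParseError, ValidationError
from thermoshift.hydropathy import (
    KYTE_DOOLITTLE,
    HydropathyProfile,
    ProteinSequence,
    gravy,
    hydropathy_profile,
    low_hydropathy_segments,
    read_fasta,
)

residues = st.text(alphabet=sorted(KYTE_DOOLITTLE), min_size=1, max_size=80)


class TestReadFasta:
    def test_single_record(self):
        seqs = read_fasta(io.StringIO(">p1\nMKVLAVGILA\n"))
        assert len(seqs) == 1
        assert len(seqs[0]) == 10

    def test_two_records_in_order(self):
        seqs = read_fasta(io.StringIO(">a\nMK\n>b\nVL\n"))
        assert [s.id for s in seqs] == ["a", "b"]

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ParseError, match="B"):
            read_fasta(io.StringIO(">x\nMKB\n"))

    def test_permissive_flag_allows_nonstandard(self):
        seqs = read_fasta(io.StringIO(">x\nMKB\n"), permissive=True)
        assert seqs[0].residues == "MKB"

    def test_empty_file_rejected(self):
        with pytest.raises(ParseError):
            read_fasta(io.StringIO(""))

    def test_case_normalized(self):
        seqs = read_fasta(io.StringIO(">x\nmkvl\n"))
        assert seqs[0].residues == "MKVL"


class TestGravy:
    def test_homopolymer_alanine(self):
        assert gravy(ProteinSequence("a", "AAAA")) == pytest.approx(1.8)

    def test_gi_pair(self):
        assert gravy(ProteinSequence("gi", "GI")) == pytest.approx(2.05)

    @given(residues)
    def test_matches_biopython_protparam(self, seq):
        # independent implementation of the same statistic
        ours = gravy(ProteinSequence("x", seq))
        theirs = ProteinAnalysis(seq).gravy()
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_unknown_residue_raises_or_zero(self):
        with pytest.raises(ValidationError):
            gravy(ProteinSequence("x", "AX"))
        assert gravy(ProteinSequence("x", "AX"), permissive=True) == pytest.approx(0.9)

    @given(residues, residues)
    def test_concatenation_is_length_weighted_mean(self, a, b):
        ga = gravy(ProteinSequence("a", a))
        gb = gravy(ProteinSequence("b", b))
        gab = gravy(ProteinSequence("ab", a + b))
        expected = (ga * len(a) + gb * len(b)) / (len(a) + len(b))
        assert gab == pytest.approx(expected, abs=1e-9)


class TestHydropathyProfile:
    def test_window_one_is_per_residue_scale(self):
        seq = ProteinSequence("x", "MKVLAV")
        profile = hydropathy_profile(seq, window=1)
        np.testing.assert_allclose(profile.scores,
                                   [KYTE_DOOLITTLE[aa] for aa in seq.residues])
        np.testing.assert_array_equal(profile.positions, np.arange(1, 7))

    def test_homopolymer_constant_profile(self):
        profile = hydropathy_profile(ProteinSequence("x", "L" * 30), window=9)
        np.testing.assert_allclose(profile.scores, KYTE_DOOLITTLE["L"])
        assert profile.scores.size == 30 - 9 + 1

    @given(residues.filter(lambda s: len(s) >= 9))
    def test_profile_bounded_by_scale_extremes(self, seq):
        profile = hydropathy_profile(ProteinSequence("x", seq), window=9)
        assert np.all(profile.scores >= -4.5 - 1e-12)
        assert np.all(profile.scores <= 4.5 + 1e-12)

    @given(residues)
    def test_window_one_mean_equals_gravy(self, seq):
        profile = hydropathy_profile(ProteinSequence("x", seq), window=1)
        assert profile.scores.mean() == pytest.approx(gravy(ProteinSequence("x", seq)))

    @given(residues.filter(lambda s: len(s) >= 2))
    def test_reversal_reverses_window_one_profile(self, seq):
        fwd = hydropathy_profile(ProteinSequence("x", seq), window=1)
        rev = hydropathy_profile(ProteinSequence("x", seq[::-1]), window=1)
        np.testing.assert_allclose(rev.scores, fwd.scores[::-1])

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            hydropathy_profile(ProteinSequence("x", "MKVLAV"), window=4)

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValidationError):
            hydropathy_profile(ProteinSequence("x", "MKV"), window=9)

    def test_center_positions(self):
        profile = hydropathy_profile(ProteinSequence("x", "A" * 20), window=9)
        assert profile.positions[0] == 5
        assert profile.positions[-1] == 16


class TestLowHydropathySegments:
    @staticmethod
    def _profile(scores):
        scores = np.asarray(scores, dtype=float)
        return HydropathyProfile(sequence_id="x", window=1,
                                 positions=np.arange(1, scores.size + 1),
                                 scores=scores, gravy=float(scores.mean()))

    def test_all_above_threshold_empty(self):
        assert low_hydropathy_segments(self._profile([0.0] * 20), threshold=-1.5) == []

    def test_single_run_detected(self):
        scores = [0.0] * 5 + [-2.0] * 12 + [0.0] * 5
        segments = low_hydropathy_segments(self._profile(scores), threshold=-1.5,
                                           min_length=10)
        assert segments == [(6, 17, pytest.approx(-2.0))]

    def test_two_runs_split_by_one_window(self):
        scores = [-2.0] * 4 + [0.0] + [-2.0] * 4
        segments = low_hydropathy_segments(self._profile(scores), threshold=-1.5,
                                           min_length=3)
        assert [(s, e) for s, e, _ in segments] == [(1, 4), (6, 9)]

    def test_short_runs_filtered(self):
        scores = [-2.0] * 5 + [0.0] * 10
        assert low_hydropathy_segments(self._profile(scores), threshold=-1.5,
                                       min_length=6) == []


def test_bundled_p65_probe_screen():
    """The bundled p65 stand-in shows the screen's qualitative picture:
    a moderately hydrophilic protein whose long low-hydropathy stretch
    falls in the disordered C-terminal half, away from the aa 1-306
    probe region."""
    from thermoshift.analysis_helpers import load_p65_sequence

    seq = load_p65_sequence()
    assert len(seq) == 551
    profile = hydropathy_profile(seq, window=9)
    assert -0.6 < profile.gravy < -0.3
    segments = low_hydropathy_segments(profile, threshold=-1.5, min_length=10)
    assert segments, "expected at least one long low-hydropathy segment"
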