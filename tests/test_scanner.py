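"""uORF scanning, extent classification, Kozak and conservation calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from utrvar.scanner import (
    ConservationTrack,
    UtrSequence,
    classify_orf_extent,
    conservation_gate,
    kozak_class,
    peptide_identity_class,
    scan_uorfs,
)

from _oracles import brute_force_identity, brute_force_uorfs

PREFIX = "ATGGCTGCTGCTGCTGCTGCTGCTGCTGCT"


def utr(seq: str, prefix: str = PREFIX) -> UtrSequence:
    return UtrSequence(seq=seq, cds_prefix=prefix)


class TestScanUorfs:
    def test_fixture_architecture(self, fixture_utr):
        """The fixture reproduces both uORFs: 7-aa in-frame MPSAGPA ending
        63 nt before the mAUG and 5-aa out-of-frame MRALP ending 2 nt
        before it."""
        u1, u2 = scan_uorfs(fixture_utr)
        assert (u1.peptide, u1.cap_to_uaug, u1.stop_to_maug_gap, u1.frame_vs_morf) == (
            "MPSAGPA", 122, 63, "in_frame",
        )
        assert (u2.peptide, u2.cap_to_uaug, u2.stop_to_maug_gap, u2.frame_vs_morf) == (
            "MRALP", 189, 2, "out_of_frame",
        )

    def test_no_atg_yields_empty(self):
        assert scan_uorfs(utr("AAATTTCCC")) == []

    def test_stop_ending_at_minus1_counts_contained(self):
        # ATG AAA TAA with the stop's last base at c.-1
        s = "C" * 10 + "ATGAAATAA"
        (u,) = scan_uorfs(utr(s))
        assert u.stop_to_maug_gap == 0

    def test_stopless_atg_not_contained(self):
        s = "C" * 10 + "ATGAAACCC"  # reads through to the CDS
        assert scan_uorfs(utr(s)) == []

    def test_matches_brute_force_on_random_utrs(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            L = int(rng.integers(50, 401))
            s = "".join(rng.choice(list("ACGT"), size=L))
            got = [(u.start_offset, u.end_offset, u.peptide) for u in scan_uorfs(utr(s))]
            assert got == brute_force_uorfs(s)

    def test_inframe_iff_distance_divisible_by_three(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            L = int(rng.integers(60, 200))
            s = "".join(rng.choice(list("ACGT"), size=L))
            for u in scan_uorfs(utr(s)):
                assert (u.frame_vs_morf == "in_frame") == ((L - u.start_offset) % 3 == 0)

    def test_rejects_degenerate_bases(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            utr("ACGTN")


class TestOrfExtent:
    def test_fixture_uaug1_contained(self, fixture_utr):
        assert classify_orf_extent(fixture_utr, 122) == "contained_uorf"

    def test_nte_construct(self):
        # ATG in frame with the mAUG, nothing but non-stop codons between
        s = "C" * 9 + "ATG" + "GCA" * 4  # (L - 9) % 3 == 0
        assert (len(s) - 9) % 3 == 0
        assert classify_orf_extent(utr(s), 9) == "n_terminal_extension"

    def test_oorf_construct(self):
        s = "C" * 10 + "ATG" + "GCAG"  # out of frame, no stop
        assert classify_orf_extent(utr(s), 10) == "overlapping_oorf"

    def test_requires_atg(self, fixture_utr):
        with pytest.raises(ValueError, match="no ATG"):
            classify_orf_extent(fixture_utr, 0)


class TestKozak:
    @pytest.mark.parametrize(
        "context, expected",
        [
            ("GCCATGG", "strong"),  # consensus at -3 and +4
            ("GCCATGC", "moderate"),  # G at -3, C at +4: the uORF situation
            ("TTTATGC", "weak"),
            ("ACCATGT", "moderate"),
        ],
    )
    def test_classes(self, context, expected):
        assert kozak_class(context, 3).strength == expected

    @given(st.text(alphabet="ACGT", min_size=7, max_size=7))
    @settings(max_examples=100, deadline=None)
    def test_pure_function_of_two_bases(self, ctx):
        """Permuting every base except -3 and +4 never changes the class."""
        seq = ctx[:3] + "ATG" + ctx[6]
        base = kozak_class(seq, 3)
        for b1 in "ACGT":
            for b2 in "ACGT":
                seq2 = ctx[0] + b1 + b2 + "ATG" + ctx[6]
                assert kozak_class(seq2, 3).strength == base.strength

    def test_incomplete_context_flagged(self):
        call = kozak_class("ATGG", 0)
        assert call.incomplete and call.strength == "moderate"
        call = kozak_class("GCCATG", 3)
        assert call.incomplete


class TestConservationGate:
    def _uorf(self, fixture_utr):
        return scan_uorfs(fixture_utr)[0]

    def test_basewise_pass(self, fixture_utr):
        u = self._uorf(fixture_utr)
        track = ConservationTrack(
            basewise={o: 3.0 for o in range(u.start_offset, u.end_offset + 1)}
        )
        g = conservation_gate(u, track)
        assert g.conserved_start is True and g.conserved_stop is True

    def test_one_low_base_fails_without_elementwise(self, fixture_utr):
        u = self._uorf(fixture_utr)
        scores = {o: 3.0 for o in range(u.start_offset, u.end_offset + 1)}
        scores[u.start_offset + 1] = 1.9
        elem = {o: 0.5 for o in scores}
        g = conservation_gate(u, ConservationTrack(basewise=scores, elementwise=elem))
        assert g.conserved_start is False and g.conserved_stop is True

    def test_elementwise_alone_can_pass(self, fixture_utr):
        u = self._uorf(fixture_utr)
        elem = {o: 0.95 for o in range(u.start_offset, u.end_offset + 1)}
        g = conservation_gate(u, ConservationTrack(elementwise=elem))
        assert g.conserved_start is True

    def test_partial_coverage_leaves_flags_absent(self, fixture_utr):
        u = self._uorf(fixture_utr)
        g = conservation_gate(u, ConservationTrack(basewise={u.start_offset: 5.0}))
        assert g.conserved_start is None

    def test_absent_track(self, fixture_utr):
        g = conservation_gate(self._uorf(fixture_utr), None)
        assert g.conserved_start is None and g.conserved_stop is None


class TestPeptideIdentity:
    @pytest.mark.parametrize(
        "peptides, pct, klass",
        [
            (["MPSAGPA", "MPSAGPA"], 100.0, "high"),
            (["MRALP", "MRTLP"], 80.0, "high"),  # exactly 80 -> high
            (["AAAA", "AATT"], 50.0, "moderate"),  # exactly 50 -> moderate
            (["AAAA", "TTTT"], 0.0, "weak"),
        ],
    )
    def test_examples(self, peptides, pct, klass):
        assert peptide_identity_class(peptides) == (pytest.approx(pct), klass)

    def test_double_gap_columns_excluded(self):
        pct, _ = peptide_identity_class(["MR-LP", "MR-TP"])
        assert pct == pytest.approx(75.0)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY-")
        for _ in range(50):
            n = int(rng.integers(2, 6))
            length = int(rng.integers(3, 12))
            peps = ["".join(rng.choice(aas, size=length)) for _ in range(n)]
            pct, _ = peptide_identity_class(peps)
            assert pct == pytest.approx(brute_force_identity(peps))

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            peptide_identity_class(["MRALP"])
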