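import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtail.tdmd import (
    DEFAULT_ENERGY,
    STACK_TABLE,
    DuplexHit,
    Transcript,
    duplex_mfe,
    find_seed_sites,
    rank_triggers,
    screen_transcripts,
    seed_site_string,
)
from mirtail._seq import revcomp

from conftest import LET7A
from oracles import brute_force_mfe, naive_seed_scan

rna_st = st.text(alphabet="ACGU", min_size=1, max_size=8)


class TestSeedSites:
    def test_let7_m8_site_string(self):
        assert seed_site_string(LET7A, "7mer-m8") == "CUACCUC"

    def test_single_site_found(self):
        t = "AAAA" + "CUACCUC" + "GGGG"
        assert find_seed_sites(LET7A, t) == [(4, "7mer-m8")]

    def test_no_sites(self):
        assert find_seed_sites(LET7A, "AAAAAAAAAAAA") == []

    def test_a1_site_requires_trailing_a(self):
        site = seed_site_string(LET7A, "7mer-A1")
        assert site == revcomp(LET7A[1:7]) + "A"
        t = "GG" + site + "GG"
        assert find_seed_sites(LET7A, t, ("7mer-A1",)) == [(2, "7mer-A1")]

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        mirna=st.text(alphabet="ACGU", min_size=16, max_size=24),
        transcript=st.text(alphabet="ACGU", min_size=7, max_size=60),
        seed_type=st.sampled_from(["7mer-m8", "7mer-A1"]),
    )
    def test_equals_naive_oracle(self, mirna, transcript, seed_type):
        got = [s for s, _ in find_seed_sites(mirna, transcript, (seed_type,))]
        assert got == naive_seed_scan(mirna, transcript, seed_type)


class TestDuplexMfe:
    def test_no_complementarity_no_duplex(self):
        assert duplex_mfe("AAAA", "AAAA") is None

    def test_perfect_gc_duplex_hand_sum(self):
        # GCGC/GCGC pairs fully; energy = initiation + 3 stack terms
        expected = (
            DEFAULT_ENERGY.initiation
            + STACK_TABLE[("G", "C", "C", "G")]
            + STACK_TABLE[("C", "G", "G", "C")]
            + STACK_TABLE[("G", "C", "C", "G")]
        )
        assert duplex_mfe("GCGC", "GCGC") == pytest.approx(expected)

    def test_single_weak_pair_positive_is_no_duplex(self):
        # lone A:U pair cannot beat the initiation penalty
        assert duplex_mfe("A", "U") is None

    def test_too_long_raises(self):
        with pytest.raises(ValueError, match="max_len"):
            duplex_mfe("A" * 61, "U" * 10)

    @settings(max_examples=250, derandomize=True, deadline=None)
    @given(a=rna_st, b=rna_st)
    def test_dp_equals_bruteforce(self, a, b):
        got = duplex_mfe(a, b)
        expected = brute_force_mfe(a, b, DEFAULT_ENERGY)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(a=rna_st, b=rna_st)
    def test_symmetric_under_strand_exchange(self, a, b):
        assert duplex_mfe(a, b) == pytest.approx(duplex_mfe(b, a))

    def test_extension_never_raises_mfe(self, rng):
        # appending/prepending bases leaves all original structures intact
        for _ in range(25):
            n1, n2 = rng.integers(4, 15, size=2)
            a = "".join(rng.choice(list("ACGU"), n1))
            b = "".join(rng.choice(list("ACGU"), n2))
            base = duplex_mfe(a, b)
            if base is None:
                continue
            for ext in ("A" + a, a + "A", "C" + a + "C"):
                assert duplex_mfe(ext, b) <= base + 1e-9
            for ext in ("G" + b, b + "G"):
                assert duplex_mfe(a, ext) <= base + 1e-9


class TestRankTriggers:
    def _hit(self, tid, mfe, abundance):
        return DuplexHit("mir", tid, 0, 7, "7mer-m8", mfe, abundance)

    def test_lower_mfe_first(self):
        ranked = rank_triggers([self._hit("a", -10, 1), self._hit("b", -30, 1)])
        assert [h.transcript_id for h in ranked] == ["b", "a"]

    def test_tie_broken_by_abundance(self):
        ranked = rank_triggers([self._hit("a", -10, 5), self._hit("b", -10, 100)])
        assert [h.transcript_id for h in ranked] == ["b", "a"]

    def test_final_tie_lexicographic(self):
        ranked = rank_triggers([self._hit("b", -10, 5), self._hit("a", -10, 5)])
        assert [h.transcript_id for h in ranked] == ["a", "b"]


class TestScreen:
    def test_extensive_pairing_beats_seed_only(self, rng):
        """A transcript complementary beyond the seed gets strictly lower MFE."""
        extensive = Transcript("extensive", "GG" + revcomp(LET7A) + "GG", 10.0)
        site = seed_site_string(LET7A, "7mer-m8")
        seed_only = Transcript(
            "seedonly",
            "ACAGAACAAGAGACAAACGAAAGAAACAAGAAACAGAAA"[:32] + site + "ACGAA",
            10.0,
        )
        hits = screen_transcripts("let-7a", LET7A, [extensive, seed_only])
        assert {h.transcript_id for h in hits} == {"extensive", "seedonly"}
        assert hits[0].transcript_id == "extensive"
        by_id = {h.transcript_id: h.mfe for h in hits}
        assert by_id["extensive"] < by_id["seedonly"]

    def test_low_expression_flagged_but_retained(self):
        t = Transcript("low", "GG" + revcomp(LET7A) + "GG", 0.2)
        hits = screen_transcripts("let-7a", LET7A, [t], min_cpm=1.0)
        assert hits and hits[0].low_expression


@pytest.mark.skipif(shutil.which("RNAduplex") is None,
                    reason="ViennaRNA not installed")
def test_ordering_agrees_with_rnaduplex_on_extensive_vs_seed_only():
    """Optional cross-check: both models must rank the extensively paired
    target as more stable than a seed-only target."""
    extensive = "GG" + revcomp(LET7A) + "GG"
    site = seed_site_string(LET7A, "7mer-m8")
    seed_only = "ACAGAACAAGAGACAAACGAAAGAAACAAGAA" + site + "ACGAA"

    def vienna_mfe(a, b):
        out = subprocess.run(
            ["RNAduplex"], input=f"{a}\n{b}\n", capture_output=True, text=True,
            check=True,
        ).stdout
        return float(out.strip().rsplit("(", 1)[1].rstrip(")"))

    ours = {s: duplex_mfe(LET7A, s) for s in (extensive, seed_only)}
    vienna = {s: vienna_mfe(LET7A, s) for s in (extensive, seed_only)}
    assert ours[extensive] < ours[seed_only]
    assert vienna[extensive] < vienna[seed_only]
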