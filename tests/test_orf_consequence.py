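"""ORF scanning, Kozak grading, start selection, NMD rule and motif scan."""

import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from splicevar.annotation_io import GenomicInterval, TranscriptModel
from splicevar.orf_consequence import (
    OrfCall,
    kozak_class,
    nmd_candidate,
    scan_c2h2,
    scan_orfs,
    select_start,
    translate,
)

STOPS = ("TAA", "TAG", "TGA")


def orf_oracle(seq, min_aa=0):
    """Brute-force three-frame AUG-to-first-stop scanner."""
    out = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in STOPS:
                n_aa = (j + 3 - i) // 3 - 1
                if n_aa >= min_aa:
                    out.append((i, j + 3))
                break
    return out


class TestScanOrfs:
    def test_minimal_orf(self):
        calls = scan_orfs("ATGAAATAA", min_protein_aa=0)
        assert len(calls) == 1
        assert calls[0].protein_length_aa == 2
        assert calls[0].stop_offset == 9

    def test_nested_orfs_share_the_stop(self):
        seq = "ATGAAA" + "ATG" + "AAA" * 5 + "TAA"
        calls = scan_orfs(seq, min_protein_aa=0)
        assert len(calls) == 2
        assert calls[0].stop_offset == calls[1].stop_offset

    def test_orf_without_stop_is_not_reported(self):
        assert scan_orfs("ATGAAAAAA", min_protein_aa=0) == []

    def test_min_protein_length_filters(self):
        assert scan_orfs("ATGAAATAA", min_protein_aa=30) == []

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = random.Random(5)
        for _ in range(120):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randrange(9, 300)))
            got = [(c.start_offset, c.stop_offset) for c in scan_orfs(seq, min_protein_aa=0)]
            assert got == orf_oracle(seq)

    def test_protein_length_invariant(self):
        rng = random.Random(6)
        for _ in range(50):
            seq = "".join(rng.choice("ACGT") for _ in range(200))
            for c in scan_orfs(seq, min_protein_aa=0):
                assert c.protein_length_aa * 3 + 3 == c.stop_offset - c.start_offset


class TestKozak:
    @pytest.mark.parametrize(
        "context,expected",
        [
            ("GCCACCATGG", "strong"),    # A at -3 and G at +4
            ("TTTTTTATGC", "weak"),      # neither
            ("TTTCTTATGG", "adequate"),  # +4 only
            ("GCCACCATGC", "adequate"),  # -3 only
        ],
    )
    def test_examples(self, context, expected):
        assert kozak_class(context, context.index("ATG", 3)) == expected

    def test_out_of_range_positions_do_not_match(self):
        assert kozak_class("ATGC", 0) == "weak"
        assert kozak_class("ATGG", 0) == "adequate"

    def test_non_aug_offset_is_a_contract_error(self):
        with pytest.raises(ValueError):
            kozak_class("AAAAAA", 0)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 3), st.sampled_from("ACGT"))
    def test_invariant_under_mutation_outside_key_positions(self, pos, base):
        ctx = list("GCCACCATGGAA")
        if pos == 3:  # -3 position: skip, that one may change the class
            return
        ctx[pos] = base
        assert kozak_class("".join(ctx), 6) == "strong"


class TestSelectStart:
    def _call(self, start, stop, kozak):
        return OrfCall(start, stop, kozak, (stop - start) // 3 - 1)

    def test_five_prime_first_with_kozak_gating(self):
        weak = self._call(0, 300, "weak")
        good = self._call(30, 300, "adequate")
        assert select_start([weak, good]) is good

    def test_fallback_when_all_weak(self):
        a, b = self._call(0, 300, "weak"), self._call(30, 300, "weak")
        assert select_start([b, a]) is a

    def test_longest_orf_policy(self):
        short = self._call(0, 33, "strong")
        long_ = self._call(60, 600, "weak")
        assert select_start([short, long_], policy="longest_orf") is long_

    def test_empty_is_noncoding_signal(self):
        with pytest.raises(ValueError, match="noncoding"):
            select_start([])


class TestNmdRule:
    def _model(self, exon_lengths):
        exons, pos = [], 0
        for n in exon_lengths:
            exons.append(GenomicInterval("c", pos, pos + n))
            pos += n + 50
        return TranscriptModel("t", "g", exons=exons)

    def _orf(self, stop_offset):
        return OrfCall(stop_offset - 39, stop_offset, "weak", 12)

    def test_stop_60_nt_upstream_of_last_junction(self):
        model = self._model([160, 60])  # last junction at offset 160
        assert nmd_candidate(model, self._orf(100)) is True

    def test_stop_exactly_50_nt_upstream_is_not_a_candidate(self):
        model = self._model([160, 60])
        assert nmd_candidate(model, self._orf(110)) is False
        assert nmd_candidate(model, self._orf(109)) is True

    def test_stop_in_last_exon(self):
        model = self._model([160, 60])
        assert nmd_candidate(model, self._orf(200)) is False

    def test_single_exon_never_a_candidate(self):
        model = self._model([400])
        assert nmd_candidate(model, self._orf(100)) is False

    def test_rule_width_is_configurable(self):
        model = self._model([160, 60])
        assert nmd_candidate(model, self._orf(110), rule_nt=49) is True


def c2h2_match_at(p, i):
    """Shortest admissible spacer expansion at one position, regex-free."""
    for n1 in (2, 3, 4):
        for n2 in (3, 4, 5):
            L = 16 + n1 + n2
            if i + L > len(p):
                continue
            s = p[i : i + L]
            if (
                s[0] == "C"
                and s[1 + n1] == "C"
                and s[5 + n1] in "LIVMFYWC"
                and s[14 + n1] == "H"
                and s[15 + n1 + n2] == "H"
            ):
                return L
    return None


def c2h2_oracle(p):
    hits, i = [], 0
    while i < len(p):
        L = c2h2_match_at(p, i)
        if L is None:
            i += 1
        else:
            hits.append((i + 1, i + L))
            i += L
    return hits


class TestC2H2Scan:
    def test_minimal_pattern_instance(self):
        assert [(h.start_aa, h.end_aa) for h in scan_c2h2("CAACAAAFAAAAAAAAHAAAH")] == [
            (1, 21)
        ]

    def test_poly_a_has_no_hits(self):
        assert scan_c2h2("A" * 50) == []

    def test_matches_brute_force_oracle(self):
        rng = random.Random(9)
        for _ in range(150):
            p = "".join(rng.choice("CHLAF") for _ in range(rng.randrange(10, 120)))
            got = [(h.start_aa, h.end_aa) for h in scan_c2h2(p)]
            assert got == c2h2_oracle(p)

    def test_overlapping_mode_is_a_superset(self):
        p = "CAACAAAFAAAAAAAAHAAAH" * 3
        non = {(h.start_aa, h.end_aa) for h in scan_c2h2(p)}
        over = {(h.start_aa, h.end_aa) for h in scan_c2h2(p, overlapping=True)}
        assert non <= over

    def test_counts_a_tandem_zinc_finger_array(self):
        finger = "CAACAAAFAAAAAAAAHAAAH"
        assert len(scan_c2h2(finger * 14)) == 14


class TestTranslate:
    def test_terminal_stop_is_dropped(self):
        assert translate("ATGAAATAA") == "MK"
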