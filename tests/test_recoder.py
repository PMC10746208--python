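"""Unit and property tests for hit finding and synonymous recoding."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stealth import (
    CodingSequence,
    OrientationMode,
    candidate_edits,
    find_hits,
    recode_cds,
    reverse_complement,
    synonymous_codons,
    translate_cds,
    verify_recode,
)
from stealth.errors import CdsValidationError, EmptyBlacklistError
from stealth.recoder import MotifHit, Orientation, RecodeResult, Substitution

from conftest import naive_find_offsets, random_dna


class TestFindHits:
    def test_single_site(self):
        hits = find_hits("AAGAATTCAA", {"GAATTC"})
        assert [(h.start, h.end) for h in hits] == [(2, 8)]

    def test_overlapping_occurrences(self):
        hits = find_hits("AAAAAA", {"AAAA"})
        assert [h.start for h in hits] == [0, 1, 2]

    def test_matches_all_offsets_oracle(self):
        seq = random_dna(300, seed=21)
        motifs = {"GATC", "GAATTC", "CCGG"}
        hits = find_hits(seq, motifs)
        expect = sorted(
            (i, m) for m in motifs for i in naive_find_offsets(seq, m)
        )
        assert [(h.start, h.motif) for h in hits] == expect

    def test_reverse_complement_orientation(self):
        # GGTACC's revcomp is itself-adjacent case: use a non-palindrome.
        seq = "AA" + reverse_complement("GCCGAT") + "AA"
        assert find_hits(seq, {"GCCGAT"}, "forward_only") == []
        hits = find_hits(seq, {"GCCGAT"}, "both")
        assert len(hits) == 1
        assert hits[0].orientation is Orientation.REVERSE_COMPLEMENT

    def test_palindrome_reported_once(self):
        hits = find_hits("AAGGATCCAA", {"GGATCC"}, "both")
        assert len(hits) == 1

    def test_empty_blacklist_rejected(self):
        with pytest.raises(EmptyBlacklistError):
            find_hits("ACGT", set())


class TestSynonymousCodons:
    @pytest.mark.parametrize(
        "codon,expected",
        [
            ("GCT", {"GCA", "GCC", "GCG"}),  # alanine four-fold box
            ("ATG", set()),  # methionine is unique
            ("TGG", set()),  # tryptophan is unique
            ("TTA", {"TTG", "CTT", "CTC", "CTA", "CTG"}),  # leucine six-fold
            ("TAA", {"TAG", "TGA"}),  # stop identity preserved
        ],
    )
    def test_table_11_families(self, codon, expected):
        assert synonymous_codons(codon, 11) == expected

    def test_families_partition_sense_codons(self):
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[11]
        for codon, aa in table.forward_table.items():
            for alt in synonymous_codons(codon):
                assert table.forward_table[alt] == aa


class TestCandidateEdits:
    def test_wobble_edit_preferred(self):
        cds = CodingSequence("t", "ATGGCATCGTAA")
        hit = find_hits(cds.seq, {"CATC"})[0]
        cands = candidate_edits(cds, hit, {"CATC"})
        first = cands[0]
        assert len(first) == 1
        assert first[0].position == 5
        assert (first[0].ref_base, first[0].alt_base) == ("A", "C")
        assert first[0].codon_position == 3

    def test_no_synonymous_escape(self):
        # ATG ATG TGG: hit spans only Met/Trp codons -> nothing can change.
        cds = CodingSequence("t", "ATGATGTGGTAA")
        hit = MotifHit(motif="TGTGG", start=4)
        assert cds.seq[4:9] == "TGTGG"
        assert candidate_edits(cds, hit, {"TGTGG"}) == []

    def test_candidates_never_create_new_hits(self):
        blacklist = {"GCCT", "CATC", "GGAT"}
        for seed in range(10):
            from stealth import generate_toy_cds

            cds = generate_toy_cds(20, [("CATC", 5)], seed=seed)
            for hit in find_hits(cds.seq, blacklist):
                for cand in candidate_edits(cds, hit, blacklist):
                    chars = list(cds.seq)
                    for s in cand:
                        chars[s.position] = s.alt_base
                    edited = "".join(chars)
                    before = {(h.start, h.motif) for h in find_hits(cds.seq, blacklist)}
                    after = {(h.start, h.motif) for h in find_hits(edited, blacklist)}
                    assert after <= before
                    assert (hit.start, hit.motif) not in after

    def test_start_codon_protected(self):
        cds = CodingSequence("t", "ATGGTATCGTAA")
        hit = MotifHit(motif="ATGG", start=0)
        for cand in candidate_edits(cds, hit, {"ATGG"}):
            assert all(s.position >= 3 for s in cand)


class TestRecodeCds:
    def test_no_hits_is_identity(self):
        cds = CodingSequence("t", "ATGGCATCGTAA")
        res = recode_cds(cds, {"TTTTTT"})
        assert res.recoded_seq == cds.seq
        assert res.substitutions == []
        assert res.status == "clean"

    def test_toy_single_wobble(self):
        cds = CodingSequence("t", "ATGGCATCGTAA")
        res = recode_cds(cds, {"CATC"})
        assert res.recoded_seq == "ATGGCCTCGTAA"
        assert len(res.substitutions) == 1
        assert res.status == "clean"
        assert translate_cds(res.recoded_seq) == translate_cds(cds.seq)
        assert find_hits(res.recoded_seq, {"CATC"}) == []

    def test_cascading_hits_converge(self):
        # Removing GCAT via the wobble G->C at codon 1 would write GCC,
        # whose context creates CCT... choose a pair that genuinely cascades:
        # blacklist both the original word and the word the first-choice edit
        # would produce, forcing the search to pick an alternative.
        cds = CodingSequence("t", "ATGGCATCGTAA")
        res = recode_cds(cds, {"CATC", "GCCT"})
        rep = verify_recode(cds, res, {"CATC", "GCCT"})
        assert res.status == "clean"
        assert rep.passed

    def test_unresolvable_hit_reported_partial(self):
        cds = CodingSequence("t", "ATGATGTGGTAA")
        res = recode_cds(cds, {"TGTGG"})
        assert res.status == "partial"
        assert [h.motif for h in res.residual_hits] == ["TGTGG"]
        assert res.recoded_seq == cds.seq
        rep = verify_recode(cds, res, {"TGTGG"})
        assert rep.passed

    def test_deterministic(self):
        from stealth import generate_toy_cds

        cds = generate_toy_cds(40, [("GAATTC", 10), ("CATC", 20)], seed=3)
        r1 = recode_cds(cds, {"GAATTC", "CATC"})
        r2 = recode_cds(cds, {"GAATTC", "CATC"})
        assert r1 == r2

    def test_idempotent_on_clean_output(self):
        from stealth import generate_toy_cds

        cds = generate_toy_cds(40, [("GAATTC", 10)], seed=5)
        res = recode_cds(cds, {"GAATTC"})
        assert res.status == "clean"
        again = recode_cds(
            CodingSequence("t2", res.recoded_seq), {"GAATTC"}
        )
        assert again.recoded_seq == res.recoded_seq
        assert again.substitutions == []

    def test_orientation_both_removes_rc_hits(self):
        from stealth import generate_toy_cds

        motif = "GCCGAT"
        rc = reverse_complement(motif)
        cds = generate_toy_cds(30, [(rc, 8)], seed=11)
        res = recode_cds(cds, {motif}, orientation_mode=OrientationMode.BOTH)
        assert res.status == "clean"
        assert find_hits(res.recoded_seq, {motif}, "both") == []
        assert translate_cds(res.recoded_seq) == cds.translate()

    def test_invalid_cds_rejected(self):
        with pytest.raises(CdsValidationError):
            CodingSequence("bad", "ATGTAAGCGTAA")  # internal stop
        with pytest.raises(CdsValidationError):
            CodingSequence("bad", "ATGGCG")  # no terminal stop

    @given(seed=st.integers(min_value=0, max_value=500))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_translation_always_preserved(self, seed):
        from stealth import generate_toy_cds

        cds = generate_toy_cds(25, [("CATC", 6)], seed=seed)
        res = recode_cds(cds, {"CATC", "GGATCC", "GCGC"})
        assert translate_cds(res.recoded_seq) == cds.translate()
        if res.status == "clean":
            assert find_hits(res.recoded_seq, {"CATC", "GGATCC", "GCGC"}) == []


class TestVerifyRecode:
    def _toy(self):
        cds = CodingSequence("t", "ATGGCATCGTAA")
        return cds, recode_cds(cds, {"CATC"})

    def test_passes_on_honest_result(self):
        cds, res = self._toy()
        assert verify_recode(cds, res, {"CATC"}).passed

    def test_detects_unlisted_base_change(self):
        cds, res = self._toy()
        corrupted = RecodeResult(
            recoded_seq=res.recoded_seq[:-4] + "TTAA",  # extra silent-ish edit
            substitutions=list(res.substitutions),
            residual_hits=[],
            status="clean",
        )
        report = verify_recode(cds, corrupted, {"CATC"})
        assert not report.checks["ledger_complete"]
        assert not report.passed

    def test_detects_non_synonymous_change(self):
        cds, res = self._toy()
        seq = list(res.recoded_seq)
        seq[4] = "T"  # GCC -> GTC, Ala -> Val
        corrupted = RecodeResult(
            recoded_seq="".join(seq),
            substitutions=res.substitutions
            + [Substitution(4, "C", "T", 1, 2)],
            residual_hits=[],
            status="clean",
        )
        report = verify_recode(cds, corrupted, {"CATC"})
        assert not report.checks["translation_identity"]
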