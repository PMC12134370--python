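"""ngRNA candidates, rPE3b post-edit-only logic, and off-target scanning."""

import pytest

from rpekit import (
    EditSpec,
    ReferenceLocus,
    SpacerSite,
    find_ngrna,
    find_spacer_sites,
    rpe3b_candidates,
    scan_offtargets,
    suggest_pam_insertion,
)
from rpekit._seq import revcomp
from rpekit.synthdata import random_locus

from .oracles import naive_offtarget_scan

CORE = "ACATACTTACTTACTTAACC"  # 20-nt protospacer, no internal GG/CC


def _locus_with_opposite_site(gap: int):
    """+ primary site at 0 plus one - strand site placed downstream.

    The - strand site is encoded as CCN + revcomp(protospacer) on the
    reference.
    """
    filler = "ATATATATATATATATATATATATATATATATATATATAT"
    seq = CORE + "AGG" + filler[:gap] + "CCT" + revcomp(CORE) + "ATAT"
    return ReferenceLocus("dual", seq)


class TestFindNgRNA:
    def test_offset_arithmetic(self):
        locus = _locus_with_opposite_site(18)
        primary = SpacerSite(locus, "+", 0)
        edit = EditSpec.substitution(10, locus.seq[10], "G")
        cands = find_ngrna(locus, primary, edit, min_offset=20, max_offset=120)
        assert len(cands) == 1
        c = cands[0]
        assert c.site.strand == "-"
        # hand-checked: CCT PAM at 23+18=41, protospacer starts at 44,
        # nick = 44+3 = 47; primary nick 17 -> offset +30
        assert c.site.proto_start == 44
        assert c.nick_offset == 47 - 17 == 30
        assert not c.overlaps_edit

    def test_no_opposite_pam_gives_empty(self):
        locus = ReferenceLocus("solo", CORE + "AGG" + "ATATATA")
        primary = SpacerSite(locus, "+", 0)
        edit = EditSpec.substitution(10, locus.seq[10], "G")
        assert find_ngrna(locus, primary, edit) == []

    def test_offset_bounds_filter(self):
        locus = _locus_with_opposite_site(18)
        primary = SpacerSite(locus, "+", 0)
        edit = EditSpec.substitution(10, locus.seq[10], "G")
        assert find_ngrna(locus, primary, edit, min_offset=40, max_offset=120) == []
        assert len(find_ngrna(locus, primary, edit, min_offset=20, max_offset=35)) == 1

    def test_edit_overlap_excluded_unless_rpe3b(self):
        locus = _locus_with_opposite_site(18)
        primary = SpacerSite(locus, "+", 0)
        # edit inside the - candidate's protospacer [44, 64)
        pos = 50
        edit = EditSpec.substitution(pos, locus.seq[pos], "G" if locus.seq[pos] != "G" else "C")
        assert find_ngrna(locus, primary, edit, 20, 120) == []
        kept = find_ngrna(locus, primary, edit, 20, 120, rpe3b=True)
        assert len(kept) == 1 and kept[0].overlaps_edit


class TestRpe3bCandidates:
    def test_edit_creating_pam_flagged_post_edit_only(self):
        # - strand candidate whose reference CC PAM is broken pre-edit (CA)
        filler = "ATATATATATATATATATATAT"
        seq = CORE + "AGG" + filler + "CAT" + revcomp(CORE) + "ATAT"
        locus = ReferenceLocus("x", seq)
        primary = SpacerSite(locus, "+", 0)
        pam_pos = 23 + len(filler) + 1  # the A of "CAT" -> C completes CC
        edit = EditSpec.substitution(pam_pos, "A", "C")
        pre = rpe3b_candidates(locus, edit, primary, min_offset=5, max_offset=120)
        hits = [c for c in pre if c.post_edit_only]
        assert len(hits) == 1
        assert hits[0].site.proto_start == 23 + len(filler) + 3

    def test_silent_edit_not_flagged(self):
        locus = _locus_with_opposite_site(18)
        primary = SpacerSite(locus, "+", 0)
        edit = EditSpec.substitution(10, locus.seq[10], "G")  # inside primary spacer
        cands = rpe3b_candidates(locus, edit, primary, min_offset=5, max_offset=120)
        assert cands and all(not c.post_edit_only for c in cands)

    def test_pre_edit_matching_candidate_false_even_if_post_matches(self):
        locus = _locus_with_opposite_site(18)
        primary = SpacerSite(locus, "+", 0)
        edit = EditSpec.substitution(10, locus.seq[10], "G")
        for c in rpe3b_candidates(locus, edit, primary, min_offset=5, max_offset=120):
            assert not c.post_edit_only  # matches both pre and post


class TestSuggestPamInsertion:
    def test_one_substitution_completes_cc(self):
        # the primary reverse window contains "CA", one substitution away
        # from the "CC" of a - strand candidate PAM (CCN on the reference)
        seq = "T" * 10 + "ACATACTTACTTCATTAACC" + "AGG" + "ATATATATATATATATATAT"
        locus = ReferenceLocus("pamins", seq)
        sites = find_spacer_sites(locus)
        primary = next(s for s in sites if s.strand == "+")
        edit_pos = primary.nick - 2
        edit = EditSpec.substitution(
            edit_pos, locus.seq[edit_pos], "G" if locus.seq[edit_pos] != "G" else "T"
        )
        sugg = suggest_pam_insertion(locus, primary, edit, max_extra_subs=2)
        assert sugg, "expected at least one PAM-completion suggestion"
        best = sugg[0]
        assert best["n_extra"] <= 2
        assert best["candidate"].post_edit_only
        # combined edit applies cleanly and contains the original alt allele
        combined = best["combined"]
        assert combined is not None
        edited = combined.apply(locus.seq)
        assert edited[edit_pos] == edit.alt_allele

    def test_at_only_window_one_sub_impossible(self):
        # window is pure A/T: completing a CC PAM needs two substitutions
        seq = "T" * 6 + "ATATATATATATATATATAT" + "AGG" + "ATATATATATATATATATATAT"
        locus = ReferenceLocus("x", seq)
        primary = next(s for s in find_spacer_sites(locus) if s.strand == "+")
        edit_pos = primary.nick - 2
        # alt G cannot contribute to an opposite-strand CC PAM
        edit = EditSpec.substitution(edit_pos, locus.seq[edit_pos], "G")
        assert suggest_pam_insertion(locus, primary, edit, max_extra_subs=1) == []
        assert suggest_pam_insertion(locus, primary, edit, max_extra_subs=2) != []

    def test_exhaustive_neighborhood_oracle(self):
        """Every suggestion's substitution set must create a post-edit-only
        candidate, verified by brute-force application of the edits."""
        seq = "T" * 10 + "ACATACTTACTTCATTAACC" + "AGG" + "ATATATATATATATATATAT"
        locus = ReferenceLocus("x", seq)
        primary = next(s for s in find_spacer_sites(locus) if s.strand == "+")
        edit_pos = primary.nick - 2
        edit = EditSpec.substitution(edit_pos, locus.seq[edit_pos], "G")
        for s in suggest_pam_insertion(locus, primary, edit, max_extra_subs=2):
            combined_seq = edit.apply(locus.seq)
            for extra in s["extra_edits"]:
                p = extra.start
                assert combined_seq[p] == extra.ref_allele
                combined_seq = combined_seq[:p] + extra.alt_allele + combined_seq[p + 1 :]
            # the edited sequence must now contain the candidate's site
            cand_sites = {
                (c.strand, c.proto_start)
                for c in find_spacer_sites(ReferenceLocus("t", combined_seq))
            }
            cs = s["candidate"].site
            assert (cs.strand, cs.proto_start) in cand_sites


class TestScanOfftargets:
    def test_perfect_planted_site(self):
        locus = random_locus(1, 500)
        spacer = "ACATACTTACTTACTTAACC"
        seq = locus.seq[:200] + spacer + "TGG" + locus.seq[200:]
        hits = scan_offtargets(seq, spacer, 0)
        assert any(h.proto_start == 200 and h.mismatch_count == 0 for h in hits)

    def test_mismatch_threshold(self):
        spacer = "ACATACTTACTTACTTAACC"
        mutated = "ACATACTTACTTACTTAACC"
        mutated = "TCATACGTACTTACTTAACA"  # 3 mismatches at 1,7,20
        subject = "T" * 50 + mutated + "TGG" + "T" * 50
        hits3 = scan_offtargets(subject, spacer, 3)
        assert any(h.mismatch_count == 3 and h.mismatch_positions == (1, 7, 20) for h in hits3)
        hits2 = scan_offtargets(subject, spacer, 2)
        assert not any(h.proto_start == 50 for h in hits2)

    @pytest.mark.parametrize("seed", [11, 12])
    def test_agrees_with_naive_oracle(self, seed):
        locus = random_locus(seed, 4000)
        spacer = locus.seq[100:120]
        got = [
            (h.strand, h.proto_start, h.mismatch_count)
            for h in scan_offtargets(locus.seq, spacer, 3)
        ]
        assert got == naive_offtarget_scan(locus.seq, spacer, 3)

    def test_monotone_in_max_mismatch(self):
        locus = random_locus(13, 5000)
        spacer = locus.seq[40:60]
        counts = [len(scan_offtargets(locus.seq, spacer, k)) for k in range(5)]
        assert counts == sorted(counts)

    def test_minus_strand_hit_orientation(self):
        spacer = "ACATACTTACTTACTTAACC"
        subject = "A" * 30 + "CCA" + revcomp(spacer) + "A" * 30
        hits = scan_offtargets(subject, spacer, 0)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-" and h.proto_start == 33
        assert h.matched[:20] == spacer
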