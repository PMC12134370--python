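"""rpegRNA/pegRNA construction: extension identity, enumeration, accessories."""

import pytest

from rpekit import (
    EditSpec,
    ReferenceLocus,
    append_motif,
    assemble_rpegrna,
    circular_parts,
    cloning_oligos,
    design_canonical_pegrna,
    design_pbs,
    design_rtt,
    enumerate_designs,
    find_spacer_sites,
)
from rpekit._seq import revcomp, to_dna, to_rna
from rpekit.design import DesignError

from .conftest import random_site_and_edit
from .oracles import simulate_primer_extension


class TestDesignPBS:
    def test_plus_strand_is_pam_side_window(self, toy_locus, toy_site):
        assert design_pbs(toy_site, toy_locus, 13) == to_rna(toy_locus.seq[17:30])

    def test_three_nt_pbs_is_protospacer_18_20(self, toy_locus, toy_site):
        # the 3-nt single-strand primer region at protospacer positions 18-20
        assert design_pbs(toy_site, toy_locus, 3) == to_rna(toy_locus.seq[17:20])

    def test_pbs_anneals_to_primer_terminus(self, toy_locus, toy_site):
        # independent route: reverse complement of the targeted-strand
        # primer's 3'-terminal bases
        primer = revcomp(toy_locus.seq[toy_site.nick :])
        assert to_dna(design_pbs(toy_site, toy_locus, 8)) == revcomp(primer[-8:])

    def test_minus_strand_symmetry(self, toy_locus, toy_site):
        rc_locus = ReferenceLocus("rc", revcomp(toy_locus.seq))
        rc_site = next(s for s in find_spacer_sites(rc_locus) if s.strand == "-")
        assert design_pbs(rc_site, rc_locus, 9) == design_pbs(toy_site, toy_locus, 9)

    def test_boundary_overflow_names_deficit(self, toy_locus, toy_site):
        with pytest.raises(DesignError, match="1 nt"):
            design_pbs(toy_site, toy_locus, 14)  # 13 nt available after nick


class TestDesignRTT:
    def test_substitution_window(self, toy_locus, toy_site, toy_sub):
        edited = toy_sub.apply(toy_locus.seq)
        assert design_rtt(toy_site, toy_locus, toy_sub, 13) == to_rna(edited[4:17])

    def test_insertion_at_nick_span(self, toy_locus, toy_site):
        ins = EditSpec.insertion(17, "T")
        rtt = design_rtt(toy_site, toy_locus, ins, 10)
        assert len(rtt) == 10
        # covered reference span is 9: the RTT is the edited window [8, 18e)
        assert rtt == to_rna(ins.apply(toy_locus.seq)[8:18])

    def test_edit_outside_reach_errors(self, toy_site, toy_locus):
        pos = 2  # label +15, beyond L_RTT 10
        edit = EditSpec.substitution(pos, toy_locus.seq[pos], "A" if toy_locus.seq[pos] != "A" else "C")
        with pytest.raises(DesignError):
            design_rtt(toy_site, toy_locus, edit, 10)

    def test_homology_shortfall_errors(self, toy_site, toy_locus):
        pos = 8  # label +9; L_RTT 10 leaves only 1 nt homology
        edit = EditSpec.substitution(pos, toy_locus.seq[pos], "A" if toy_locus.seq[pos] != "A" else "C")
        with pytest.raises(DesignError, match="homology"):
            design_rtt(toy_site, toy_locus, edit, 10, min_post_edit_homology=5)


class TestExtensionIdentity:
    """Core oracle: the assembled extension must drive a simulated primer
    extension that reproduces the EditSpec exactly."""

    @pytest.mark.parametrize("seed", range(40))
    def test_substitutions_match_edited_window(self, seed):
        locus, site, edit = random_site_and_edit(seed, edit_kind="substitution")
        d = assemble_rpegrna(site, edit, L_PBS=12, L_RTT=14)
        edited = edit.apply(locus.seq)
        nick = site.nick
        # direct identity: RTT+PBS equals edited NTS window as RNA
        assert d.extension_rna == to_rna(edited[nick - 14 : nick + 12])
        assert simulate_primer_extension(d)

    @pytest.mark.parametrize("seed", range(40, 60))
    @pytest.mark.parametrize("kind", ["insertion", "deletion"])
    def test_indel_edits_flap_simulation(self, seed, kind):
        locus, site, edit = random_site_and_edit(seed, edit_kind=kind)
        d = assemble_rpegrna(site, edit, L_PBS=12, L_RTT=14)
        assert simulate_primer_extension(d)

    def test_minus_strand_designs(self, toy_locus, toy_site, toy_sub):
        rc_locus = ReferenceLocus("rc", revcomp(toy_locus.seq))
        rc_site = next(s for s in find_spacer_sites(rc_locus) if s.strand == "-")
        n = len(toy_locus)
        a, b = toy_sub.ref_span
        rc_edit = EditSpec.substitution(
            n - b, revcomp(toy_sub.ref_allele), revcomp(toy_sub.alt_allele)
        )
        d = assemble_rpegrna(rc_site, rc_edit, L_PBS=10, L_RTT=12)
        assert simulate_primer_extension(d)
        # mirror of the + strand design on the original locus
        d_fwd = assemble_rpegrna(toy_site, toy_sub, L_PBS=10, L_RTT=12)
        assert d.extension_rna == d_fwd.extension_rna

    def test_spacer_is_protospacer_as_rna(self, toy_site, toy_locus, toy_sub):
        d = assemble_rpegrna(toy_site, toy_sub, 10, 12)
        assert d.spacer_rna == to_rna(toy_site.spacer)
        assert d.full_sequence.startswith(d.spacer_rna + d.scaffold_rna)
        assert d.full_sequence.endswith(d.rtt_rna + d.pbs_rna)


class TestCanonicalPegRNA:
    def test_window_membership(self, toy_locus, toy_site):
        # protospacer position 18 (ref index 17) = canonical +1
        e18 = EditSpec.substitution(17, toy_locus.seq[17], "A" if toy_locus.seq[17] != "A" else "C")
        d = design_canonical_pegrna(toy_site, e18, 10, 8)
        assert d.mode == "canonical"
        with pytest.raises(DesignError):
            assemble_rpegrna(toy_site, e18, 10, 8)
        # protospacer position 17 (ref index 16) = reverse +1
        e17 = EditSpec.substitution(16, toy_locus.seq[16], "A" if toy_locus.seq[16] != "A" else "C")
        assert assemble_rpegrna(toy_site, e17, 10, 8).mode == "reverse"
        with pytest.raises(DesignError):
            design_canonical_pegrna(toy_site, e17, 10, 8)

    def test_extension_is_revcomp_of_edited_window(self, toy_locus, toy_site):
        e = EditSpec.substitution(18, toy_locus.seq[18], "A" if toy_locus.seq[18] != "A" else "C")
        d = design_canonical_pegrna(toy_site, e, 12, 9)
        edited = e.apply(toy_locus.seq)
        nick = toy_site.nick
        assert d.extension_rna == to_rna(revcomp(edited[nick - 12 : nick + 9]))

    @pytest.mark.parametrize("seed", range(60, 75))
    def test_flap_simulation_oracle(self, seed):
        locus, site, edit = random_site_and_edit(seed, mode="canonical")
        d = design_canonical_pegrna(site, edit, 11, 13)
        # canonical flap replaces the non-targeted strand right of the nick
        flap = d.flap_dna
        edited = edit.apply(locus.seq)
        nick = site.nick
        assert flap == edited[nick : nick + d.L_RTT]


class TestEnumerateDesigns:
    def test_default_ranges_give_49_rows(self, toy_site, toy_sub):
        df = enumerate_designs(toy_site, toy_sub)
        assert len(df) == 49
        assert df["rank"].tolist() == list(range(1, 50))

    def test_gc_flags_and_ranking(self, toy_site, toy_sub):
        df = enumerate_designs(toy_site, toy_sub)
        ok = df[df["gc_pass"]]
        assert ((ok["pbs_gc"] >= 40) & (ok["pbs_gc"] <= 60)).all()
        assert ((ok["rtt_gc"] >= 40) & (ok["rtt_gc"] <= 60)).all()
        # GC-pass block strictly precedes flagged rows
        flags = df["gc_pass"].tolist()
        assert flags == sorted(flags, reverse=True) or not any(flags)

    def test_poly_a_pbs_all_fail_with_zero_gc(self):
        seq = "ACATACTTACTTACTTAACC" + "AGG" + "A" * 20
        locus = ReferenceLocus("polyA", seq)
        site = next(s for s in find_spacer_sites(locus) if s.strand == "+" and s.proto_start == 0)
        edit = EditSpec.substitution(10, seq[10], "G")
        df = enumerate_designs(site, edit)
        done = df[df["error"] == ""]
        assert len(done) > 0
        # PBS covers ref[17:17+L]: "CCAGGAAA..." mostly A beyond; longest PBS still <40%
        assert not done["gc_pass"].any()

    def test_deterministic(self, toy_site, toy_sub):
        a = enumerate_designs(toy_site, toy_sub)
        b = enumerate_designs(toy_site, toy_sub)
        assert a.equals(b)


class TestAccessories:
    def test_append_motif_suffix_and_immutability(self, toy_site, toy_sub):
        d = assemble_rpegrna(toy_site, toy_sub, 10, 12)
        e = append_motif(d, linker="AAUU", motif="CGCGG")
        assert e.full_sequence.endswith("AAUU" + "CGCGG")
        assert d.motif_rna is None  # original unchanged
        assert append_motif(d, linker="", motif="CGCGG").full_sequence.endswith(
            d.extension_rna + "CGCGG"
        )
        with pytest.raises(DesignError, match="already"):
            append_motif(e)

    def test_circular_parts_conserve_components(self, toy_site, toy_sub):
        d = assemble_rpegrna(toy_site, toy_sub, 10, 12)
        parts = circular_parts(d, {"five_prime": "GGG", "three_prime": "UUU"})
        roles = dict(parts)
        assert roles["guide"] == d.spacer_rna + d.scaffold_rna
        assert roles["cassette"] == "GGG" + d.rtt_rna + d.pbs_rna + "UUU"
        bare = dict(circular_parts(d, {}))
        assert bare["cassette"] == d.extension_rna

    def test_oligos_interior_complementary(self, toy_site, toy_sub):
        d = assemble_rpegrna(toy_site, toy_sub, 10, 12)
        oligos = cloning_oligos(d)
        for top, bottom in oligos.values():
            assert bottom[4:] == revcomp(top[4:])

    def test_five_prime_g_policy(self, toy_site, toy_sub):
        d = assemble_rpegrna(toy_site, toy_sub, 10, 12)
        spacer_dna = to_dna(d.spacer_rna)
        assert not spacer_dna.startswith("G")
        top, bottom = cloning_oligos(d, prepend_g=True)["spacer"]
        assert top[4:] == "G" + spacer_dna
        assert bottom[4:] == revcomp("G" + spacer_dna)
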