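"""Hairpin scanning, stem scoring and cleavage geometry."""

import pytest

from parecall.structure import (
    Hairpin,
    StructureError,
    check_geometry,
    reverse_complement,
    scan_hairpins,
    stem_score,
    tetraloop_pfm,
)

# G/C-only arms ending in G: the loop is the only [AU]GNN match
ARM14 = "GGCGGCGCGGCCGG"
ARM18 = "GCGGCGGCGCGGCCGCGG"


def hairpin_seq(arm=ARM14, loop="AGGA", pad5="", pad3=""):
    return pad5 + arm + loop + reverse_complement(arm) + pad3


class TestScanHairpins:
    def test_constructed_stem_found_exactly(self):
        (hp,) = scan_hairpins(hairpin_seq())
        assert hp.loop_seq == "AGGA"
        assert hp.n_pairs == 14
        assert hp.bulges == 0

    def test_poly_a_has_no_stem(self):
        assert scan_hairpins("A" * 80) == []

    def test_ugau_loop_matches_the_au_gnn_consensus(self):
        (hp,) = scan_hairpins(hairpin_seq(loop="UGAU"))
        assert hp.loop_seq == "UGAU"

    def test_cgaa_loop_rejected_by_default_but_found_permissive(self):
        seq = hairpin_seq(loop="CGAA")
        assert scan_hairpins(seq) == []
        permissive = scan_hairpins(seq, loop_pattern="NGNN")
        assert any(h.loop_seq == "CGAA" and h.n_pairs == 14 for h in permissive)

    def test_dna_input_treated_as_rna(self):
        (hp,) = scan_hairpins(hairpin_seq().replace("U", "T"))
        assert hp.loop_seq == "AGGA"

    def test_non_nucleotide_characters_rejected(self):
        with pytest.raises(StructureError):
            scan_hairpins("ACGUXACGU")

    def test_min_stem_bp_threshold(self):
        assert scan_hairpins(hairpin_seq(), min_stem_bp=15) == []

    def test_interior_bulge_is_skipped_and_counted(self):
        arm = "GCGGCGGCGGCGCG"
        right = reverse_complement(arm)
        bulged = right[:7] + "A" + right[7:]  # 1-nt insertion, cannot pair
        (hp,) = scan_hairpins(arm + "AGGA" + bulged)
        assert hp.n_pairs == 14
        assert hp.bulges == 1

    def test_mirror_image_hairpins_at_mirrored_coordinates(self):
        seq = hairpin_seq(pad5="AAAAA", pad3="CCCCCCCC")
        fwd = scan_hairpins(seq, loop_pattern="NNNN")
        rev = scan_hairpins(reverse_complement(seq), loop_pattern="NNNN")
        assert fwd and rev
        n = len(seq)
        rev_loops = {(h.loop_start, h.loop_end) for h in rev}
        for h in fwd:
            assert (n - h.loop_end, n - h.loop_start) in rev_loops

    def test_most_stable_hairpin_ranked_first(self):
        strong = hairpin_seq(arm=ARM14)
        weak = hairpin_seq(arm="AUAUAUAUAUAUAU", loop="UGCC")
        hairpins = scan_hairpins(strong + "CCCCC" + weak)
        assert hairpins[0].loop_seq == "AGGA"  # all-GC stem outranks AU stem
        scores = [stem_score(h) for h in hairpins]
        assert scores == sorted(scores)


class TestStemScore:
    def test_four_gc_pairs(self):
        hp = Hairpin("GGGGAGGACCCC", 4, 8, pairs=[(3, 8), (2, 9), (1, 10), (0, 11)])
        assert stem_score(hp) == -12.0

    def test_adding_an_au_pair(self):
        hp = Hairpin(
            "AGGGGAGGACCCCU", 5, 9,
            pairs=[(4, 9), (3, 10), (2, 11), (1, 12), (0, 13)],
        )
        assert stem_score(hp) == -14.0

    def test_invariant_under_pair_reordering(self):
        pairs = [(3, 8), (2, 9), (1, 10), (0, 11)]
        a = Hairpin("GGGGAGGACCCC", 4, 8, pairs=pairs)
        b = Hairpin("GGGGAGGACCCC", 4, 8, pairs=list(reversed(pairs)))
        assert stem_score(a) == stem_score(b)

    def test_bulges_penalized(self):
        hp = Hairpin("GGGGAGGACCCC", 4, 8, pairs=[(3, 8), (2, 9)], bulged={1})
        assert stem_score(hp) == -4.0

    def test_pair_disrupting_substitution_destabilizes(self):
        intact = hairpin_seq(arm=ARM18)
        pos = len(ARM18) + 4 + 3  # third base of the 3' arm
        mutated = intact[:pos] + "A" + intact[pos + 1:]
        best = lambda seq: min(stem_score(h) for h in scan_hairpins(seq, min_stem_bp=8))
        assert best(mutated) > best(intact)

    def test_empty_pair_list_rejected(self):
        with pytest.raises(StructureError):
            stem_score(Hairpin("AGGA", 0, 4))


class TestCheckGeometry:
    @pytest.fixture
    def stem18(self):
        seq = hairpin_seq(arm=ARM18, pad5="AAAAAA", pad3="AAAAAA")
        (hp,) = scan_hairpins(seq)
        assert hp.n_pairs == 18
        return hp

    def test_canonical_minus14_plus16(self, stem18):
        report = check_geometry(stem18, site5=stem18.loop_start - 14,
                                site3=stem18.loop_end + 16)
        assert (report.dist5, report.dist3, report.overhang3) == (14, 16, 2)
        assert report.canonical

    def test_single_downstream_cut_is_canonical(self, stem18):
        report = check_geometry(stem18, site3=stem18.loop_end + 16)
        assert report.dist3 == 16 and report.dist5 is None and report.overhang3 is None
        assert report.canonical

    def test_minus10_plus20_not_canonical(self, stem18):
        report = check_geometry(stem18, site5=stem18.loop_start - 10,
                                site3=stem18.loop_end + 20)
        assert (report.dist5, report.dist3) == (10, 20)
        assert not report.canonical

    def test_bulged_nucleotides_excluded_from_distance(self):
        hp = Hairpin("N" * 60, loop_start=30, loop_end=34, pairs=[(29, 34)],
                     bulged={20, 40})
        report = check_geometry(hp, site5=15, site3=51)
        assert report.dist5 == 14  # genomic 15 minus one bulge
        assert report.dist3 == 16  # genomic 17 minus one bulge
        assert report.overhang3 == 2 and report.canonical

    def test_requires_a_cut_and_bounds(self, stem18):
        with pytest.raises(StructureError):
            check_geometry(stem18)
        with pytest.raises(StructureError):
            check_geometry(stem18, site3=len(stem18.window) + 5)

    def test_perfect_stem_overhang_identity(self, stem18):
        """-14/+16 cuts around a 4-nt loop always imply a 2-nt 3' overhang."""
        for d5 in (13, 14, 15):
            report = check_geometry(stem18, site5=stem18.loop_start - d5,
                                    site3=stem18.loop_end + d5 + 2)
            assert report.overhang3 == 2


class TestTetraloopPFM:
    def test_consensus_positions(self):
        aligned = ["GGC" + loop + "GCC" for loop in ("AGGA", "AGUU", "AGGU")]
        pfm = tetraloop_pfm(aligned)
        freqs = pfm.frequencies()
        assert freqs.loc["L1", "A"] == 1.0
        assert freqs.loc["L2", "G"] == 1.0
        assert (pfm.counts.sum(axis=1) == pfm.n_loops).all()

    def test_single_loop_is_one_hot(self):
        pfm = tetraloop_pfm(["GGCAGGAGCC"])
        assert (pfm.counts.max(axis=1) == 1).all()
        assert pfm.counts.to_numpy().sum() == 10

    def test_generator_drawn_loops_keep_g_at_position_two(self):
        import numpy as np

        rng = np.random.default_rng(0)
        loops = [
            "GGC" + rng.choice(["A", "U"]) + "G" + "".join(rng.choice(list("ACGU"), 2)) + "GCC"
            for _ in range(42)
        ]
        pfm = tetraloop_pfm(loops)
        assert pfm.n_loops == 42
        assert pfm.frequencies().loc["L2", "G"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructureError):
            tetraloop_pfm(["AGGA"])
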