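"""Collapse, pairing, classification, clustering and decay quantification."""

import numpy as np
import pytest

from parecall.annotation import AnnotationSet, Feature
from parecall.sites import (
    cluster_substrates,
    collapse_secondary,
    compare_site_sets,
    classify_site,
    degradome_fraction,
    netseq_concordance,
    pair_sites,
)

from conftest import make_normalized, make_site


class TestCollapseSecondary:
    def test_nibbled_satellite_flagged_secondary(self):
        a = make_site(100, wt_cpm=(100, 100))
        b = make_site(102, wt_cpm=(10, 10))
        out = collapse_secondary([a, b])
        assert not a.is_secondary and b.is_secondary
        assert out == [a, b]

    def test_gap_beyond_five_keeps_both_primary(self):
        a, b = make_site(100), make_site(106)
        collapse_secondary([a, b])
        assert not a.is_secondary and not b.is_secondary

    def test_tie_breaks_to_five_prime_most(self):
        a, b = make_site(100), make_site(101)
        collapse_secondary([a, b])
        assert not a.is_secondary and b.is_secondary
        c, d = make_site(200, "-"), make_site(201, "-")
        collapse_secondary([c, d])
        assert c.is_secondary and not d.is_secondary  # 5'-most on minus = larger

    def test_run_extends_through_consecutive_gaps(self):
        sites = [make_site(p, wt_cpm=(cpm, cpm)) for p, cpm in
                 [(100, 50), (103, 200), (106, 20)]]
        collapse_secondary(sites)
        assert [s.is_secondary for s in sites] == [True, False, True]

    def test_idempotent_with_pairing(self):
        sites = [make_site(100, wt_cpm=(100, 100)), make_site(102, wt_cpm=(10, 10)),
                 make_site(134, wt_cpm=(80, 80))]
        once = collapse_secondary(sites)
        pairs1, singles1 = pair_sites(once)
        twice = collapse_secondary(once)
        pairs2, singles2 = pair_sites(twice)
        assert [s.is_secondary for s in once] == [s.is_secondary for s in twice]
        assert [(p.site5.position, p.site3.position) for p in pairs1] == [
            (p.site5.position, p.site3.position) for p in pairs2
        ]
        assert [s.position for s in singles1] == [s.position for s in singles2]


class TestPairSites:
    def test_34nt_spacing_pairs(self):
        a, b = make_site(500), make_site(534)
        (pair,), singles = pair_sites([a, b])
        assert pair.spacing == 34
        assert pair.site5 is a and pair.site3 is b
        assert singles == [] and a.pair_id == b.pair_id

    def test_far_apart_stays_single(self):
        pairs, singles = pair_sites([make_site(500), make_site(600)])
        assert pairs == [] and len(singles) == 2

    def test_tolerance_admits_33(self):
        (pair,), _ = pair_sites([make_site(500), make_site(533)])
        assert pair.spacing == 33

    def test_minus_strand_site5_is_downstream_coordinate(self):
        a, b = make_site(500, "-"), make_site(534, "-")
        (pair,), _ = pair_sites([a, b])
        assert pair.site5 is b and pair.site3 is a  # transcript 5' = larger pos

    def test_greedy_prefers_exact_spacing_and_each_site_pairs_once(self):
        a, b, c = make_site(500), make_site(533), make_site(534)
        (pair,), singles = pair_sites([a, b, c])
        assert pair.site3.position.position == 534  # |34-34| beats |33-34|
        assert [s.position.position for s in singles] == [533]

    def test_secondary_sites_excluded(self):
        a, b = make_site(500), make_site(534)
        b.is_secondary = True
        pairs, singles = pair_sites([a, b])
        assert pairs == [] and singles == [a]


@pytest.fixture
def annotation():
    return AnnotationSet(
        [
            Feature("chrI", 100, 200, "+", "CDS", "g1"),
            Feature("chrI", 50, 100, "+", "five_prime_UTR", "g1"),
            Feature("chrI", 200, 250, "+", "three_prime_UTR", "g1"),
            Feature("chrI", 400, 500, "+", "ncRNA", "n1"),
            Feature("chrI", 400, 500, "+", "CDS", "g2"),
            Feature("chrI", 600, 700, "+", "intron", "g3"),
        ]
    )


class TestClassifySite:
    def test_cds_site(self, annotation):
        site = make_site(150)
        assert classify_site(site, annotation) == "mRNA_CDS"
        assert site.gene == "g1"

    def test_opposite_strand_only_is_antisense(self, annotation):
        assert classify_site(make_site(150, "-"), annotation) == "antisense"

    def test_no_overlap_is_intergenic(self, annotation):
        assert classify_site(make_site(300), annotation) == "intergenic"

    def test_ncrna_takes_precedence_over_cds(self, annotation):
        assert classify_site(make_site(450), annotation) == "ncRNA"

    def test_intron_and_utr_categories(self, annotation):
        assert classify_site(make_site(650), annotation) == "intron"
        assert classify_site(make_site(75), annotation) == "five_prime_UTR"
        assert classify_site(make_site(225), annotation) == "three_prime_UTR"


class TestClusterSubstrates:
    def test_sites_in_one_gene_form_one_substrate(self, annotation):
        sites = [make_site(120), make_site(180)]
        subs = cluster_substrates(sites, annotation)
        assert len(subs) == 1 and subs[0].substrate_id == "g1"
        assert subs[0].category == "mRNA_CDS"

    def test_single_site_single_substrate(self, annotation):
        assert len(cluster_substrates([make_site(150)], annotation)) == 1

    def test_intergenic_single_linkage_radius(self, annotation):
        near = [make_site(1000), make_site(1150)]
        assert len(cluster_substrates(near, annotation)) == 1
        far = [make_site(1000), make_site(1300)]
        assert len(cluster_substrates(far, annotation)) == 2

    def test_partition_property(self, annotation):
        rng = np.random.default_rng(3)
        sites = [make_site(int(p)) for p in rng.choice(2000, size=30, replace=False)]
        subs = cluster_substrates(sites, annotation)
        assert sum(len(s.sites) for s in subs) == len(sites)
        seen = [id(site) for sub in subs for site in sub.sites]
        assert len(seen) == len(set(seen))
        assert len(subs) <= len(sites)

    def test_mixed_category_substrate_takes_modal_category(self, annotation):
        sites = [make_site(120), make_site(150), make_site(225)]  # CDS, CDS, 3'UTR
        (sub,) = cluster_substrates(sites, annotation)
        assert sub.category == "mRNA_CDS"


class TestCompareSiteSets:
    def test_identical_sets(self):
        a = [make_site(100), make_site(500)]
        b = [make_site(100), make_site(500)]
        report = compare_site_sets(a, b)
        assert report.shared == 2 and report.a_only == 0 and report.b_only == 0
        assert report.substrate_ratio == 1.0

    def test_sevenfold_more_substrates(self):
        a = [make_site(100)]
        b = [make_site(101)] + [make_site(100 + 1000 * k) for k in range(1, 7)]
        report = compare_site_sets(a, b)
        assert report.shared == 1
        assert report.substrate_ratio == pytest.approx(7.0)

    def test_disjoint_sets(self):
        report = compare_site_sets([make_site(100)], [make_site(500)])
        assert report.shared == 0 and report.a_only == 1 and report.b_only == 1

    def test_match_window_and_strand_respected(self):
        report = compare_site_sets([make_site(100)], [make_site(102, "-")])
        assert report.shared == 0  # distance ok but strands differ


def _degradome_setup(site_cpms, tss_cpm, tss_window=5):
    length = 400
    ann = AnnotationSet(
        [
            Feature("chrI", 100, 300, "+", "CDS", "g1"),
            Feature("chrI", 50, 51, "+", "TSS", "g1"),
        ]
    )
    vec = np.zeros(length)
    vec[50] = tss_cpm
    sites = []
    for pos, cpm in site_cpms:
        vec[pos] = cpm
        sites.append(make_site(pos, wt_cpm=(cpm, cpm)))
    track = make_normalized({("chrI", "+"): vec}, {"chrI": length}, "wt")
    return degradome_fraction(track, ann, sites, tss_window)


class TestDegradomeFraction:
    def test_formula(self):
        (frac,) = _degradome_setup([(150, 90.0)], 10.0)
        assert frac.fraction == pytest.approx(0.9)

    def test_zero_endo_gives_zero(self):
        (frac,) = _degradome_setup([], 10.0)
        assert frac.fraction == 0.0

    def test_two_peaks_sum(self):
        (frac,) = _degradome_setup([(150, 30.0), (200, 30.0)], 40.0)
        assert frac.fraction == pytest.approx(0.6)

    def test_pure_endo_gives_one_and_bounds(self):
        (frac,) = _degradome_setup([(150, 55.0)], 0.0)
        assert frac.fraction == 1.0
        assert 0.0 <= frac.fraction <= 1.0

    def test_no_signal_transcript_skipped(self):
        assert _degradome_setup([], 0.0) == []


class TestNetseqConcordance:
    def _track(self, spikes, length=300):
        vec = np.zeros(length)
        for pos, value in spikes:
            vec[pos] = value
        return make_normalized({("chrI", "+"): vec, ("chrI", "-"): vec.copy()},
                               {"chrI": length}, "netseq")

    def test_spike_one_nt_upstream_is_concordant(self):
        summary = netseq_concordance([make_site(100)], self._track([(99, 50.0)]))
        assert summary.flags[0].concordant
        assert summary.fraction_concordant == 1.0

    def test_flat_track_not_concordant(self):
        summary = netseq_concordance([make_site(100)], self._track([]))
        assert not summary.flags[0].concordant

    def test_spike_at_site_itself_not_concordant(self):
        summary = netseq_concordance([make_site(100)], self._track([(100, 50.0)]))
        assert not summary.flags[0].concordant

    def test_minus_strand_checks_position_plus_one(self):
        summary = netseq_concordance([make_site(100, "-")], self._track([(101, 50.0)]))
        assert summary.flags[0].concordant

    def test_boundary_site_flagged_not_assessable(self):
        summary = netseq_concordance([make_site(0)], self._track([]))
        assert not summary.flags[0].assessable
        assert summary.n_assessable == 0
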