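"""The overlap-channel algebra: orthogonality, polarity, hybrid formation."""

import itertools

import pytest

from sira.att import (
    AttSite, DESIGN_OVERLAP_ORDER, INT_ONLY, INT_RDF,
    channel_of, enumerate_channels, find_att_sites, hybrid_sites, revcomp,
    sites_compatible,
)
from sira.errors import IncompatibleSitesError, ValidationError

ALL_DINUCS = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


class TestChannels:
    def test_channel_of_examples(self):
        ch = channel_of("TT")
        assert ch.representative == "AA" and not ch.symmetric
        ch = channel_of("TA")
        assert ch.representative == "TA" and ch.symmetric
        assert channel_of("CT") == channel_of("AG")

    @pytest.mark.parametrize("d", ALL_DINUCS)
    def test_revcomp_invariance(self, d):
        assert channel_of(d) == channel_of(revcomp(d))

    def test_sixteen_dinucleotides_partition_into_ten_channels(self):
        chans = enumerate_channels()
        assert len(chans) == 10
        asym = [c for c in chans if not c.symmetric]
        sym = [c for c in chans if c.symmetric]
        assert len(asym) == 6 and len(sym) == 4
        # exact partition: every dinucleotide in exactly one channel
        members = [d for c in chans for d in c.members]
        assert sorted(members) == sorted(ALL_DINUCS)
        assert all(len(c.members) == 2 for c in asym)
        assert all(len(c.members) == 1 for c in sym)

    def test_asymmetric_channels_match_published_pairs(self):
        # TT/AA, CT/AG, GT/AC, CA/TG, CC/GG, TC/GA
        got = {frozenset(c.members) for c in enumerate_channels() if not c.symmetric}
        want = {frozenset({"TT", "AA"}), frozenset({"CT", "AG"}),
                frozenset({"GT", "AC"}), frozenset({"CA", "TG"}),
                frozenset({"CC", "GG"}), frozenset({"TC", "GA"})}
        assert got == want
        assert [channel_of(d).representative for d in DESIGN_OVERLAP_ORDER] == \
            ["AA", "AG", "AC", "CA", "CC", "GA"]

    @pytest.mark.parametrize("bad", ["T", "TTT", "NN", "tx", "", 12])
    def test_invalid_overlaps_rejected(self, bad):
        with pytest.raises(ValidationError):
            channel_of(bad)


class TestCompatibility:
    def test_matched_pair_parallel(self):
        p = AttSite.make("P", "TT")
        b = AttSite.make("B", "TT")
        rep = sites_compatible(p, b, INT_ONLY)
        assert rep.compatible and rep.relative_orientation == "parallel"

    def test_reversed_complement_partner(self):
        # attP^TT recombines with a reversed attB^AA site
        p = AttSite.make("P", "TT", "forward")
        b = AttSite.make("B", "AA", "reverse")
        assert sites_compatible(p, b, INT_ONLY).compatible
        # ... but not with attB^AA in the same placement
        assert not sites_compatible(p, b.flipped(), INT_ONLY).compatible

    def test_hybrids_inert_without_rdf(self):
        l = AttSite.make("L", "TT")
        r = AttSite.make("R", "TT")
        assert not sites_compatible(l, r, INT_ONLY).compatible
        assert sites_compatible(l, r, INT_RDF).compatible

    def test_symmetric_channel_recombines_both_ways(self):
        p = AttSite.make("P", "TA")
        for orientation in ("forward", "reverse"):
            b = AttSite.make("B", "TA", orientation)
            rep = sites_compatible(p, b, INT_ONLY)
            assert rep.compatible and rep.relative_orientation == "both"

    def test_orthogonality_exhaustive(self):
        """Sites from different channels never recombine, under any
        condition, type pairing or orientation (16 x 16 overlaps)."""
        type_pairs = [("P", "B"), ("L", "R")]
        for da, db in itertools.product(ALL_DINUCS, repeat=2):
            if channel_of(da) == channel_of(db):
                continue
            for ta, tb in type_pairs:
                for oa, ob in itertools.product(("forward", "reverse"), repeat=2):
                    a = AttSite.make(ta, da, oa)
                    b = AttSite.make(tb, db, ob)
                    for cond in (INT_ONLY, INT_RDF):
                        assert not sites_compatible(a, b, cond).compatible

    def test_rdf_gating_never_enables_other_type_pairs(self):
        """RDF swaps P x B for L x R and nothing else: same-type pairs and
        hybrid/parental mixtures stay silent under both conditions."""
        dead = [("P", "P"), ("B", "B"), ("L", "L"), ("R", "R"),
                ("P", "L"), ("P", "R"), ("B", "L"), ("B", "R")]
        for ta, tb in dead:
            a = AttSite.make(ta, "TT")
            b = AttSite.make(tb, "TT")
            for cond in (INT_ONLY, INT_RDF):
                assert not sites_compatible(a, b, cond).compatible
        p, b = AttSite.make("P", "TT"), AttSite.make("B", "TT")
        l, r = AttSite.make("L", "TT"), AttSite.make("R", "TT")
        assert sites_compatible(p, b, INT_ONLY).compatible
        assert not sites_compatible(p, b, INT_RDF).compatible
        assert sites_compatible(l, r, INT_RDF).compatible
        assert not sites_compatible(l, r, INT_ONLY).compatible


class TestHybridSites:
    def test_arm_composition(self):
        p = AttSite.make("P", "TT")
        b = AttSite.make("B", "TT")
        attl, attr = hybrid_sites(p, b)
        assert attl.site_type == "L"
        assert attl.sequence == b.left_arm + "TT" + p.right_arm
        assert attr.site_type == "R"
        assert attr.sequence == p.left_arm + "TT" + b.right_arm

    def test_round_trip_regenerates_parents(self):
        p = AttSite.make("P", "GT")
        b = AttSite.make("B", "GT")
        attl, attr = hybrid_sites(p, b)
        p2, b2 = hybrid_sites(attl, attr)
        assert (p2, b2) == (p, b)

    @pytest.mark.parametrize("d", DESIGN_OVERLAP_ORDER)
    def test_overlap_conserved(self, d):
        p, b = AttSite.make("P", d), AttSite.make("B", d)
        attl, attr = hybrid_sites(p, b)
        assert attl.overlap == attr.overlap == d

    def test_incompatible_inputs_rejected(self):
        with pytest.raises(IncompatibleSitesError):
            hybrid_sites(AttSite.make("P", "TT"), AttSite.make("B", "TC"))
        with pytest.raises(IncompatibleSitesError):
            hybrid_sites(AttSite.make("P", "TT"), AttSite.make("P", "TT"))


class TestSiteDetection:
    def test_detects_composed_sites_both_strands(self):
        p = AttSite.make("P", "CA")
        b = AttSite.make("B", "TC", "reverse")
        seq = "AATTCC" + p.placed_sequence + "GGGG" + b.placed_sequence + "TT"
        hits = find_att_sites(seq)
        assert [(h["site_type"], h["overlap"], h["orientation"]) for h in hits] == \
            [("P", "CA", "forward"), ("B", "TC", "reverse")]
        assert hits[0]["start"] == 6
        assert hits[1]["end"] == len(seq) - 2

    def test_effective_overlap_and_labels(self):
        s = AttSite.make("B", "TC", "reverse")
        assert s.effective_overlap() == "GA"
        assert s.label() == "attB^TC"
        assert s.placed_sequence == revcomp(s.sequence)
        assert len(s.sequence) == 46  # arm + 2 + arm, phiC31-scale site
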