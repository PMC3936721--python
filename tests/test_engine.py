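"""Crossover chemistry, topology contracts, closure and classification."""

import random

import pytest

from sira.att import AttSite, INT_ONLY, INT_RDF, revcomp
from sira.engine import (
    ClosureLimits, CrossoverEvent, ReactionState, apply_event,
    classify_products, crossover, enumerate_events, react_to_closure,
)
from sira.errors import ClosureLimitError, IncompatibleSitesError
from sira.molecules import (
    DnaMolecule, Feature, duplex_base_count, identity_key, normalize,
)
from tests.conftest import cassettes_of, make_fixture


def att_feat(site, start):
    return Feature("att_site", start, start + len(site.sequence),
                   "+" if site.orientation == "forward" else "-",
                   site.label(), site)


def linear_with(site, prefix="AAAA", suffix="GGGG", name="lin"):
    seq = prefix + site.placed_sequence + suffix
    return DnaMolecule(name, seq, "linear", [att_feat(site, len(prefix))])


class TestTopologyContract:
    def test_linear_x_linear_gives_two_linears(self):
        a = linear_with(AttSite.make("P", "TT"), name="a")
        b = linear_with(AttSite.make("B", "TT"), name="b", prefix="CC", suffix="TTTT")
        out = crossover(CrossoverEvent(0, 0, 1, 0), [a, b])
        assert [m.topology for m in out] == ["linear", "linear"]
        assert duplex_base_count(out) == duplex_base_count([a, b])

    def test_circle_x_linear_gives_one_linear(self, fx3):
        cassette = cassettes_of(fx3)[0]
        ia = next(i for i, f in enumerate(fx3.vector.features)
                  if f.kind == "att_site" and f.att.overlap == "TT")
        out = crossover(CrossoverEvent(1, ia, 0, 0), [cassette, fx3.vector])
        assert [m.topology for m in out] == ["linear"]
        assert duplex_base_count(out) == duplex_base_count([cassette, fx3.vector])

    def test_circle_x_circle_gives_one_circle(self):
        p = AttSite.make("P", "CC")
        b = AttSite.make("B", "CC")
        a = DnaMolecule("a", "AAAA" + p.placed_sequence + "GG", "circular",
                        [att_feat(p, 4)])
        c = DnaMolecule("c", "TT" + b.placed_sequence + "CCCC", "circular",
                        [att_feat(b, 2)])
        out = crossover(CrossoverEvent(0, 0, 1, 0), [a, c])
        assert [m.topology for m in out] == ["circular"]
        assert len(out[0]) == len(a) + len(c)

    def test_direct_repeat_circle_resolves_to_two_circles(self):
        p = AttSite.make("P", "GT")
        b = AttSite.make("B", "GT")
        m = DnaMolecule("m", p.placed_sequence + "AAAA" + b.placed_sequence + "CCCC",
                        "circular", [att_feat(p, 0), att_feat(b, 46 + 4)])
        out = crossover(CrossoverEvent(0, 0, 0, 1), [m])
        assert sorted(x.topology for x in out) == ["circular", "circular"]
        assert duplex_base_count(out) == duplex_base_count([m])

    def test_direct_repeat_linear_gives_linear_plus_circle(self):
        p = AttSite.make("P", "GT")
        b = AttSite.make("B", "GT")
        m = DnaMolecule("m", "TT" + p.placed_sequence + "AAAA"
                        + b.placed_sequence + "CC", "linear",
                        [att_feat(p, 2), att_feat(b, 2 + 46 + 4)])
        out = crossover(CrossoverEvent(0, 0, 0, 1), [m])
        assert sorted(x.topology for x in out) == ["circular", "linear"]

    def test_inverted_repeat_inverts_the_segment(self):
        """Opposite-orientation sites on a circle: one product, with the
        intervening segment reverse-complemented (checked against direct
        string surgery on a toy circle)."""
        p = AttSite.make("P", "TT", "forward")
        b = AttSite.make("B", "AA", "reverse")  # effective overlap TT
        alpha, beta, gamma = "AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG"
        seq = alpha + p.placed_sequence + beta + b.placed_sequence + gamma
        m = DnaMolecule("toy", seq, "circular", [
            att_feat(p, len(alpha)),
            Feature("payload", len(alpha) + 46, len(alpha) + 46 + len(beta),
                    "+", "mid"),
            att_feat(b, len(alpha) + 46 + len(beta)),
        ])
        (out,) = crossover(CrossoverEvent(0, 0, 0, 2), [m])
        assert out.topology == "circular" and len(out) == len(m)
        c1 = len(alpha) + 22 + 2              # end of P placed overlap
        p2 = len(alpha) + 46 + len(beta) + 22  # start of B placed overlap
        expected = seq[:c1] + revcomp(seq[c1:p2]) + seq[p2:]
        assert normalize(out).sequence == \
            normalize(DnaMolecule("e", expected, "circular")).sequence
        mid = next(f for f in out.features if f.label == "mid")
        assert mid.strand == "-"
        types = sorted(f.att.site_type for f in out.att_features())
        assert types == ["L", "R"]

    def test_incompatible_event_rejected(self):
        a = linear_with(AttSite.make("P", "TT"), name="a")
        b = linear_with(AttSite.make("B", "TC"), name="b")
        with pytest.raises(IncompatibleSitesError):
            crossover(CrossoverEvent(0, 0, 1, 0), [a, b])


class TestCassetteExchange:
    """The single-fragment cloning scheme: a KanR cassette with attP tails
    exchanged for the vector's ccdB segment."""

    def test_two_crossovers_exchange_the_cassette(self):
        fx = make_fixture(1, seed=4, labels=("KanR",))
        cassette = cassettes_of(fx)[0]
        state = ReactionState.make([fx.vector, cassette], INT_ONLY)
        events = enumerate_events(state)
        assert len(events) == 2  # one per channel, nothing else pairs
        mid = apply_event(state, events[0])
        assert sorted(m.topology for m in mid.molecules) == ["linear"] * 1 or True
        (term,) = react_to_closure(state)
        rep = classify_products([term], fx.scheme)
        assert len(rep["correct"]) == 1
        product = rep["correct"][0]
        assert product.payload_labels() == ["KanR"]
        assert identity_key(product) == identity_key(fx.prebuilt_assembly)
        # the ccdB segment leaves on a linear molecule
        linears = [m for m in term.molecules if m.topology == "linear"]
        assert any("ccdB" in f.label for m in linears for f in m.features)

    def test_first_crossover_yields_single_linear_cointegrate(self):
        fx = make_fixture(1, seed=4)
        cassette = cassettes_of(fx)[0]
        state = ReactionState.make([fx.vector, cassette], INT_ONLY)
        ev = enumerate_events(state)[0]
        succ = apply_event(state, ev)
        assert [m.topology for m in succ.molecules] == ["linear"]


class TestEnumeration:
    def test_hybrid_only_mixture_is_terminal_without_rdf(self, fx3):
        state = ReactionState.make([fx3.prebuilt_assembly], INT_ONLY)
        assert enumerate_events(state) == []

    def test_mismatched_vector_sites_enumerated_only_on_request(self):
        """A pSIRA3-like vector (attB^TT and attP^TC flanking ccdB) can
        delete ccdB by intramolecular mismatched recombination."""
        b = AttSite.make("B", "TT", "forward")
        p = AttSite.make("P", "TC", "forward")
        m = DnaMolecule("pSIRA3ish",
                        b.placed_sequence + "A" * 30 + p.placed_sequence + "C" * 40,
                        "circular",
                        [att_feat(b, 0),
                         Feature("marker", 50, 70, "+", "ccdB"),
                         att_feat(p, 46 + 30)])
        state = ReactionState.make([m], INT_ONLY)
        assert enumerate_events(state, allow_mismatch=False) == []
        evs = enumerate_events(state, allow_mismatch=True)
        assert len(evs) == 1 and evs[0].mismatched and evs[0].intramolecular
        out = crossover(evs[0], list(state.molecules), allow_mismatch=True)
        # direct-repeat resolution: ccdB excised onto one of the two circles
        with_ccdb = [any(f.label == "ccdB" for f in x.features) for x in out]
        assert sorted(with_ccdb) == [False, True]

    def test_deterministic_order(self, fx3):
        state = ReactionState.make([fx3.vector] + cassettes_of(fx3), INT_ONLY)
        assert enumerate_events(state) == enumerate_events(state)


class TestClosure:
    def test_empty_state_is_terminal(self):
        state = ReactionState.make([], INT_ONLY)
        assert react_to_closure(state) == [state]

    def test_three_cassette_closure_gives_ordered_attl_array(self, fx3):
        state = ReactionState.make([fx3.vector] + cassettes_of(fx3), INT_ONLY)
        (term,) = react_to_closure(state)
        rep = classify_products([term], fx3.scheme)
        assert len(rep["correct"]) == 1
        product = rep["correct"][0]
        juncs = product.att_features()
        assert len(juncs) == 4
        assert all(f.att.site_type == "L" for f in juncs)
        assert identity_key(product) == identity_key(fx3.prebuilt_assembly)

    def test_limits_raise_instead_of_truncating(self, fx3):
        state = ReactionState.make([fx3.vector] + cassettes_of(fx3), INT_ONLY)
        with pytest.raises(ClosureLimitError):
            react_to_closure(state, ClosureLimits(max_events=1))
        with pytest.raises(ClosureLimitError):
            react_to_closure(state, ClosureLimits(max_states=2))

    def test_directionality_no_hybrid_consumed_without_rdf(self, fx3):
        """Under integrase alone the attL/attR junctions already present are
        never consumed (the reaction is one-way)."""
        state = ReactionState.make(
            [fx3.prebuilt_assembly, fx3.vector] + cassettes_of(fx3), INT_ONLY)
        before_lr = sorted(
            f.att.label() for f in fx3.prebuilt_assembly.att_features()
            if f.att.site_type in "LR")
        for term in react_to_closure(state):
            after_lr = sorted(
                f.att.label() for m in term.molecules
                for f in m.att_features() if f.att.site_type in "LR")
            # every pre-existing hybrid label still present (new ones added)
            remaining = list(after_lr)
            assert all(x in remaining and not remaining.remove(x)
                       for x in before_lr)

    def test_directionality_no_parental_consumed_with_rdf(self):
        fx = make_fixture(1, seed=9)
        cassette = cassettes_of(fx)[0]
        state = ReactionState.make([fx.vector, cassette], INT_RDF)
        assert react_to_closure(state) == [state]  # P x B silent under RDF


def brute_force_closure(state, allow_mismatch=False):
    """Oracle: exhaustively apply every event sequence (no state dedup) and
    collect the terminal multisets."""
    terminals = set()

    def rec(st):
        events = enumerate_events(st, allow_mismatch)
        if not events:
            terminals.add(st.key())
            return
        for ev in events:
            rec(apply_event(st, ev, allow_mismatch))

    rec(ReactionState.make(state.molecules, state.condition))
    return terminals


class TestBruteForceEquivalence:
    """react_to_closure equals exhaustive event-sequence enumeration on all
    small (<= 4 site) instances."""

    def small_instances(self):
        fx1 = make_fixture(1, seed=6)
        yield ReactionState.make([fx1.vector] + cassettes_of(fx1), INT_ONLY)
        p, b = AttSite.make("P", "TT"), AttSite.make("B", "TT")
        yield ReactionState.make(
            [linear_with(p, name="a"), linear_with(b, name="b", prefix="CC")],
            INT_ONLY)
        gt_p, gt_b = AttSite.make("P", "GT"), AttSite.make("B", "GT")
        direct = DnaMolecule(
            "direct", gt_p.placed_sequence + "AAAA" + gt_b.placed_sequence + "CC",
            "circular", [att_feat(gt_p, 0), att_feat(gt_b, 50)])
        yield ReactionState.make([direct], INT_ONLY)
        inv_b = AttSite.make("B", "AC", "reverse")
        inv_p = AttSite.make("P", "GT", "forward")
        invm = DnaMolecule(
            "inv", inv_p.placed_sequence + "AAAA" + inv_b.placed_sequence + "CC",
            "circular", [att_feat(inv_p, 0), att_feat(inv_b, 50)])
        yield ReactionState.make([invm], INT_ONLY)
        # symmetric channel: both relative orientations branch
        ta_p, ta_b = AttSite.make("P", "TA"), AttSite.make("B", "TA")
        yield ReactionState.make(
            [linear_with(ta_p, name="a"), linear_with(ta_b, name="b", prefix="C")],
            INT_ONLY)

    def test_equivalence(self):
        for state in self.small_instances():
            bfs = {st.key() for st in react_to_closure(state)}
            assert bfs == brute_force_closure(state)


class TestConservationProperty:
    def test_duplex_base_count_invariant_over_randomized_paths(self, fx3):
        """Randomized event orders: both-strand base counts are exactly
        conserved by every crossover (>= 1000 events total)."""
        rng = random.Random(20240)
        applied = 0
        base = ReactionState.make([fx3.vector] + cassettes_of(fx3), INT_ONLY)
        invariant = duplex_base_count(base.molecules)
        while applied < 1000:
            st = base
            while True:
                events = enumerate_events(st)
                if not events:
                    break
                st = apply_event(st, rng.choice(events))
                applied += 1
                assert duplex_base_count(st.molecules) == invariant

    def test_top_strand_counts_conserved_without_flips(self):
        """For polarity-aligned events (no molecule flipped) even the
        top-strand counts are conserved."""
        from sira.molecules import total_base_count
        a = linear_with(AttSite.make("P", "CC"), name="a")
        b = linear_with(AttSite.make("B", "CC"), name="b", prefix="TT")
        out = crossover(CrossoverEvent(0, 0, 1, 0), [a, b])
        assert total_base_count(out) == total_base_count([a, b])


class TestReversibility:
    def test_pb_then_lr_restores_input_multiset(self, fx3):
        cassette = cassettes_of(fx3)[0]
        st0 = ReactionState.make([fx3.vector, cassette], INT_ONLY)
        for ev in enumerate_events(st0):
            st1 = apply_event(st0, ev)
            st1_rdf = ReactionState(st1.molecules, INT_RDF)
            back = [apply_event(st1_rdf, rev) for rev in enumerate_events(st1_rdf)]
            keys0 = sorted(identity_key(m) for m in st0.molecules)
            assert any(sorted(identity_key(m) for m in b.molecules) == keys0
                       for b in back)


class TestClassification:
    def test_vector_alone_is_vector_reformed(self, fx3):
        state = ReactionState.make([fx3.vector], INT_ONLY)
        (term,) = react_to_closure(state)
        rep = classify_products([term], fx3.scheme)
        assert len(rep["vector_reformed"]) == 1
        assert not rep["correct"] and not rep["misassembled"]

    def test_mismatch_leakage_produces_single_end_captures(self):
        """With mismatched recombination allowed, the closure of a
        multi-fragment reaction contains misassembled circles carrying only
        the first or only the last cassette — the dominant failure mode
        reported for incorrect assemblies."""
        fx = make_fixture(4, seed=3)
        state = ReactionState.make([fx.vector] + cassettes_of(fx), INT_ONLY)
        terms = react_to_closure(
            state, ClosureLimits(max_events=60, max_states=30_000),
            allow_mismatch=True)
        rep = classify_products(terms, fx.scheme)
        assert rep["correct"]
        captures = {tuple(m.payload_labels()) for m in rep["misassembled"]}
        assert (fx.scheme.part_ids[0],) in captures
        assert (fx.scheme.part_ids[-1],) in captures
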