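"""Crossover simulation and reaction-network closure.

A crossover cuts two compatible att sites at their central 2 bp overlaps and
cross-joins the halves, forming two hybrid sites (attP x attB -> attL/attR;
attL x attR -> attP/attB with the RDF). Product topology follows the classic
site-specific recombination rules:

* intermolecular: circle x circle -> one circle; circle x linear -> one
  linear; linear x linear -> two linears (reciprocal end exchange);
* intramolecular, sites in direct repeat (same placed orientation): a circle
  resolves to two circles, a linear to one linear plus one circle;
* intramolecular, inverted repeat: the intervening segment is inverted;
  molecule count is unchanged.

The duplex (both-strand) base count is conserved exactly by every event.

Orientation semantics: a free molecule has no intrinsic orientation, so for
*intermolecular* pairs an event exists whenever the two sites share an
overlap channel (the engine flips the second molecule when the placed
polarities oppose, recording ``flip_b``). For *intramolecular* pairs the
placed effective overlaps must match; their relative placement then selects
excision (direct repeat) versus inversion. Sites on a symmetric channel
recombine in both relative alignments, so they generate two event branches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

from .att import (
    HALF_SITE_ORIGIN, JUNCTION_TYPE, AttSite, EnzymeCondition, INT_ONLY,
    revcomp, sites_compatible,
)
from .errors import ClosureLimitError, IncompatibleSitesError, ValidationError
from .molecules import DnaMolecule, Feature, identity_key, normalize

_LO = {t: HALF_SITE_ORIGIN[t][0] for t in HALF_SITE_ORIGIN}
_RO = {t: HALF_SITE_ORIGIN[t][1] for t in HALF_SITE_ORIGIN}


# --------------------------------------------------------------------------
# events and states

@dataclass(frozen=True)
class CrossoverEvent:
    """One recombination event between two att-site features.

    ``molecule_a``/``molecule_b`` index into the state's molecule list (they
    are equal for an intramolecular event); ``site_index_a``/``site_index_b``
    index into the molecule's ``features``. ``flip_b`` marks an
    intermolecular event that proceeds with molecule b flipped;
    ``alt_geometry`` marks the second alignment branch of a symmetric-channel
    intramolecular pair; ``mismatched`` marks a type-compatible event whose
    channels differ (only enumerated under ``allow_mismatch``).
    """

    molecule_a: int
    site_index_a: int
    molecule_b: int
    site_index_b: int
    condition: EnzymeCondition = INT_ONLY
    flip_b: bool = False
    alt_geometry: bool = False
    mismatched: bool = False

    @property
    def intramolecular(self) -> bool:
        return self.molecule_a == self.molecule_b


@dataclass(frozen=True)
class ClosureLimits:
    """Hard stops for reaction-network exploration."""

    max_events: int = 50        # events applied along any one path
    max_molecules: int = 200    # molecules allowed in a single state
    max_states: int = 10_000    # distinct states visited

    def __post_init__(self):
        if min(self.max_events, self.max_molecules, self.max_states) <= 0:
            raise ValidationError("closure limits must be positive")


@dataclass(frozen=True)
class ReactionState:
    """A multiset of normalized molecules plus the enzyme condition."""

    molecules: tuple[DnaMolecule, ...]
    condition: EnzymeCondition = INT_ONLY

    @classmethod
    def make(cls, molecules, condition: EnzymeCondition = INT_ONLY) -> "ReactionState":
        mols = sorted((normalize(m) for m in molecules), key=identity_key)
        return cls(tuple(mols), condition)

    def key(self) -> tuple:
        return (tuple(identity_key(m) for m in self.molecules), self.condition)


# --------------------------------------------------------------------------
# site bookkeeping

def _att_feature(mol: DnaMolecule, idx: int) -> Feature:
    try:
        f = mol.features[idx]
    except IndexError as exc:
        raise ValidationError(f"no feature {idx} on molecule {mol.id}") from exc
    if f.kind != "att_site":
        raise ValidationError(f"feature {idx} on molecule {mol.id} is not an att site")
    return f


def _cut_after_overlap(f: Feature) -> int:
    """Top-strand position just 3' of the placed overlap (may exceed L only
    for wrapped site features, which callers unwrap first)."""
    att = f.att
    up = len(att.left_arm) if att.orientation == "forward" else len(att.right_arm)
    return f.start + up + 2


def _overlap_start(f: Feature) -> int:
    return _cut_after_overlap(f) - 2


def _junction(u: AttSite, v: AttSite) -> tuple[AttSite, str]:
    """Hybrid site formed when the upstream (through-overlap) half of placed
    site ``u`` is joined to the downstream half of placed site ``v``.

    Same-orientation pairs give the canonical hybrids (attL/attR or
    attP/attB). Antiparallel pairs join like halves and yield hybrids whose
    distal arm is the reverse complement of a same-origin arm — recombination
    between opposed-polarity sites is productive in the same channel but does
    not reconstruct the canonical arm layout.
    Returns (site, strand) with strand giving feature placement.
    """
    uo, vo = u.orientation, v.orientation
    if uo == "forward" and vo == "forward":
        return AttSite(JUNCTION_TYPE[(_LO[u.site_type], _RO[v.site_type])],
                       u.overlap, u.left_arm, v.right_arm, "forward"), "+"
    if uo == "reverse" and vo == "reverse":
        return AttSite(JUNCTION_TYPE[(_LO[v.site_type], _RO[u.site_type])],
                       u.overlap, v.left_arm, u.right_arm, "reverse"), "-"
    if uo == "forward":  # v reverse: antiparallel, left-half to left-half
        return AttSite(JUNCTION_TYPE[(_LO[u.site_type], _LO[v.site_type])],
                       u.overlap, u.left_arm, revcomp(v.left_arm), "forward"), "+"
    # u reverse, v forward: right-half to right-half
    return AttSite(JUNCTION_TYPE[(_RO[u.site_type], _RO[v.site_type])],
                   revcomp(u.overlap), revcomp(u.right_arm), v.right_arm, "forward"), "+"


def _junction_feature(u: AttSite, v: AttSite, cut_pos: int) -> Feature:
    """Feature for the junction whose overlap ends at ``cut_pos`` in the
    product's coordinates."""
    site, strand = _junction(u, v)
    up_len = (len(site.left_arm) if strand == "+" else len(site.right_arm)) + 2
    down_len = len(site.right_arm) if strand == "+" else len(site.left_arm)
    return Feature("att_site", cut_pos - up_len, cut_pos + down_len,
                   strand, site.label(), site)


def _wrap_junction(f: Feature, L: int) -> Feature:
    """Re-express a junction feature on a circular product of length L
    (wrapping the origin where needed)."""
    s = f.start % L
    e = f.end % L or L
    return replace(f, start=s, end=e)


def _window_features(mol: DnaMolecule, x: int, y: int, skip: tuple[int, ...],
                     shift: int) -> list[Feature]:
    """Features of ``mol`` fully inside the non-wrapping window [x, y),
    re-based to ``shift``; consumed att features (indices in ``skip``) and
    features crossing the window edges are dropped."""
    out = []
    for i, f in enumerate(mol.features):
        if i in skip or f.wraps:
            continue
        if x <= f.start and f.end <= y:
            out.append(replace(f, start=f.start - x + shift, end=f.end - x + shift))
    return out


# --------------------------------------------------------------------------
# the crossover itself

def _event_compatibility(fa: Feature, fb: Feature, ev: CrossoverEvent,
                         allow_mismatch: bool) -> None:
    a, b = fa.att, fb.att
    cond = ev.condition
    if ev.mismatched:
        if not allow_mismatch:
            raise IncompatibleSitesError("mismatched event without allow_mismatch")
        if frozenset((a.site_type, b.site_type)) != cond.active_type_pair:
            raise IncompatibleSitesError(
                f"type pair {a.site_type}x{b.site_type} inactive under this condition")
        return
    if ev.intramolecular:
        rep = sites_compatible(a, b, cond)
        if not rep.compatible:
            raise IncompatibleSitesError(f"{a.label()} x {b.label()}: {rep.reason}")
    else:
        b_eff = b.flipped() if ev.flip_b else b
        rep = sites_compatible(a, b_eff, cond)
        if not rep.compatible:
            raise IncompatibleSitesError(
                f"{a.label()} x {b.label()} (flip_b={ev.flip_b}): {rep.reason}")


def crossover(event: CrossoverEvent, molecules: list[DnaMolecule],
              allow_mismatch: bool = False) -> list[DnaMolecule]:
    """Execute one crossover; returns the product molecules.

    ``molecules`` is the list the event's molecule indices refer to. The
    reactant molecules are consumed; every other molecule is untouched (and
    not returned). Total base count over {reactants} equals that over
    {products} exactly.
    """
    mol_a = molecules[event.molecule_a]
    if event.intramolecular:
        if event.site_index_a == event.site_index_b:
            raise ValidationError("an event needs two distinct sites")
        fa = _att_feature(mol_a, event.site_index_a)
        fb = _att_feature(mol_a, event.site_index_b)
        _event_compatibility(fa, fb, event, allow_mismatch)
        return _intramolecular(mol_a, event)
    mol_b = molecules[event.molecule_b]
    fa = _att_feature(mol_a, event.site_index_a)
    fb = _att_feature(mol_b, event.site_index_b)
    _event_compatibility(fa, fb, event, allow_mismatch)
    return _intermolecular(mol_a, event.site_index_a, mol_b, event.site_index_b,
                           event.flip_b)


def _unwrap_site(mol: DnaMolecule, idx: int) -> tuple[DnaMolecule, int]:
    """Rotate a circular molecule so the chosen att feature does not wrap."""
    f = mol.features[idx]
    if f.wraps:
        mol = mol.rotated(f.start)
        return mol, idx
    return mol, idx


def _intermolecular(mol_a: DnaMolecule, ia: int, mol_b: DnaMolecule, ib: int,
                    flip_b: bool) -> list[DnaMolecule]:
    if flip_b:
        mol_b = mol_b.reverse_complement()
    if mol_a.topology == "circular":
        mol_a, ia = _unwrap_site(mol_a, ia)
    if mol_b.topology == "circular":
        mol_b, ib = _unwrap_site(mol_b, ib)
    fa, fb = mol_a.features[ia], mol_b.features[ib]
    ca, cb = _cut_after_overlap(fa), _cut_after_overlap(fb)
    La, Lb = len(mol_a), len(mol_b)
    pid = f"{mol_a.id}x{mol_b.id}"

    if mol_a.topology == "circular" and mol_b.topology == "circular":
        a_rot = mol_a.rotated(ca)
        b_rot = mol_b.rotated(cb)
        seq = a_rot.sequence + b_rot.sequence
        feats = _window_features(a_rot, 0, La, (ia,), 0)
        feats += _window_features(b_rot, 0, Lb, (ib,), La)
        j1 = _wrap_junction(_junction_feature(fa.att, fb.att, La), La + Lb)
        j2 = _wrap_junction(_junction_feature(fb.att, fa.att, La + Lb), La + Lb)
        return [DnaMolecule(pid, seq, "circular", sorted(feats + [j1, j2],
                                                         key=lambda f: f.start))]

    if mol_a.topology != mol_b.topology:
        # one circle, one linear -> one linear with the circle inserted
        lin, il, cl = (mol_a, ia, ca) if mol_a.topology == "linear" else (mol_b, ib, cb)
        circ, ic, cc = (mol_b, ib, cb) if mol_a.topology == "linear" else (mol_a, ia, ca)
        c_rot = circ.rotated(cc)
        Lc = len(circ)
        seq = lin.sequence[:cl] + c_rot.sequence + lin.sequence[cl:]
        feats = _window_features(lin, 0, cl, (il,), 0)
        feats += _window_features(c_rot, 0, Lc, (ic,), cl)
        feats += _window_features(lin, cl, len(lin), (il,), cl + Lc)
        fl, fc = lin.features[il], circ.features[ic]
        j1 = _junction_feature(fl.att, fc.att, cl)
        j2 = _junction_feature(fc.att, fl.att, cl + Lc)
        return [DnaMolecule(pid, seq, "linear",
                            sorted(feats + [j1, j2], key=lambda f: f.start))]

    # linear x linear -> two linears
    seq1 = mol_a.sequence[:ca] + mol_b.sequence[cb:]
    feats1 = _window_features(mol_a, 0, ca, (ia,), 0)
    feats1 += _window_features(mol_b, cb, Lb, (ib,), ca)
    feats1.append(_junction_feature(fa.att, fb.att, ca))
    seq2 = mol_b.sequence[:cb] + mol_a.sequence[ca:]
    feats2 = _window_features(mol_b, 0, cb, (ib,), 0)
    feats2 += _window_features(mol_a, ca, La, (ia,), cb)
    feats2.append(_junction_feature(fb.att, fa.att, cb))
    return [
        DnaMolecule(pid + ".1", seq1, "linear", sorted(feats1, key=lambda f: f.start)),
        DnaMolecule(pid + ".2", seq2, "linear", sorted(feats2, key=lambda f: f.start)),
    ]


def _intramolecular(mol: DnaMolecule, event: CrossoverEvent) -> list[DnaMolecule]:
    i1, i2 = event.site_index_a, event.site_index_b
    if mol.topology == "circular":
        # Rotating to the start of site 1 unwraps both sites: neither can
        # cross the other's interval, so neither crosses the new origin.
        mol = mol.rotated(mol.features[i1].start)
    if mol.features[i1].start > mol.features[i2].start:
        i1, i2 = i2, i1
    f1, f2 = mol.features[i1], mol.features[i2]
    a1, a2 = f1.att, f2.att
    if event.alt_geometry:
        # second alignment branch of a symmetric channel: treat site 2 as if
        # placed the other way (its effective overlap is unchanged)
        a2 = a2.flipped()
        f2 = replace(f2, strand="-" if f2.strand == "+" else "+", att=a2)
    same_orientation = a1.orientation == a2.orientation
    L = len(mol)
    if same_orientation:
        return _intra_direct(mol, i1, i2, f1, f2, L)
    return [_intra_inversion(mol, i1, i2, f1, f2, L)]


def _intra_direct(mol, i1, i2, f1, f2, L) -> list[DnaMolecule]:
    c1, c2 = _cut_after_overlap(f1), _cut_after_overlap(f2)
    skip = (i1, i2)
    if mol.topology == "circular":
        seq1 = mol.sequence[c1:c2]
        feats1 = _window_features(mol, c1, c2, skip, 0)
        j1 = _wrap_junction(_junction_feature(f2.att, f1.att, len(seq1)), len(seq1))
        seq2 = mol.sequence[c2:] + mol.sequence[:c1]
        feats2 = _window_features(mol, c2, L, skip, 0)
        feats2 += _window_features(mol, 0, c1, skip, L - c2)
        j2 = _wrap_junction(_junction_feature(f1.att, f2.att, len(seq2)), len(seq2))
        return [
            DnaMolecule(mol.id + ".1", seq1, "circular",
                        sorted(feats1 + [j1], key=lambda f: f.start)),
            DnaMolecule(mol.id + ".2", seq2, "circular",
                        sorted(feats2 + [j2], key=lambda f: f.start)),
        ]
    # linear: deletion circle + shortened linear
    seq_lin = mol.sequence[:c1] + mol.sequence[c2:]
    feats_lin = _window_features(mol, 0, c1, skip, 0)
    feats_lin += _window_features(mol, c2, L, skip, c1)
    feats_lin.append(_junction_feature(f1.att, f2.att, c1))
    seq_circ = mol.sequence[c1:c2]
    feats_circ = _window_features(mol, c1, c2, skip, 0)
    jc = _wrap_junction(_junction_feature(f2.att, f1.att, len(seq_circ)), len(seq_circ))
    return [
        DnaMolecule(mol.id + ".lin", seq_lin, "linear",
                    sorted(feats_lin, key=lambda f: f.start)),
        DnaMolecule(mol.id + ".circ", seq_circ, "circular",
                    sorted(feats_circ + [jc], key=lambda f: f.start)),
    ]


def _intra_inversion(mol, i1, i2, f1, f2, L) -> DnaMolecule:
    a1, a2 = f1.att, f2.att
    skip = (i1, i2)
    if a1.orientation == "forward":
        x = _cut_after_overlap(f1)       # end of site-1 placed overlap
        y = _overlap_start(f2)           # start of site-2 placed overlap
        j_fwd = AttSite(JUNCTION_TYPE[(_LO[a1.site_type], _RO[a2.site_type])],
                        a1.overlap, a1.left_arm, a2.right_arm, "forward")
        j_rev = AttSite(JUNCTION_TYPE[(_LO[a2.site_type], _RO[a1.site_type])],
                        a2.overlap, a2.left_arm, a1.right_arm, "reverse")
        jf = Feature("att_site", x - len(a1.left_arm) - 2, x + len(a2.right_arm),
                     "+", j_fwd.label(), j_fwd)
        jr = Feature("att_site", y - len(a1.right_arm), y + 2 + len(a2.left_arm),
                     "-", j_rev.label(), j_rev)
    else:
        x = _overlap_start(f1)           # start of site-1 placed overlap
        y = _cut_after_overlap(f2)       # end of site-2 placed overlap
        j_rev = AttSite(JUNCTION_TYPE[(_LO[a2.site_type], _RO[a1.site_type])],
                        a2.overlap, a2.left_arm, a1.right_arm, "reverse")
        j_fwd = AttSite(JUNCTION_TYPE[(_LO[a1.site_type], _RO[a2.site_type])],
                        a1.overlap, a1.left_arm, a2.right_arm, "forward")
        jr = Feature("att_site", x - len(a2.left_arm), x + 2 + len(a1.right_arm),
                     "-", j_rev.label(), j_rev)
        jf = Feature("att_site", y - len(a1.left_arm) - 2, y + len(a2.right_arm),
                     "+", j_fwd.label(), j_fwd)
    seq = mol.sequence[:x] + revcomp(mol.sequence[x:y]) + mol.sequence[y:]
    feats = _window_features(mol, 0, x, skip, 0)
    for idx, f in enumerate(mol.features):
        if idx in skip or f.wraps:
            continue
        if x <= f.start and f.end <= y:  # inside the inverted segment
            ns, ne = x + (y - f.end), x + (y - f.start)
            att = f.att.flipped() if f.att is not None else None
            feats.append(Feature(f.kind, ns, ne,
                                 "-" if f.strand == "+" else "+", f.label, att))
    feats += _window_features(mol, y, L, skip, y)
    feats += [jf, jr]
    return DnaMolecule(mol.id + ".inv", seq, mol.topology,
                       sorted(feats, key=lambda f: f.start))


# --------------------------------------------------------------------------
# enumeration and closure

def enumerate_events(state: ReactionState, allow_mismatch: bool = False
                     ) -> list[CrossoverEvent]:
    """All crossover events available in a state, in deterministic order
    (molecules are already sorted by normal form; site pairs by index)."""
    cond = state.condition
    if not cond.integrase_present:
        return []
    events: list[CrossoverEvent] = []
    mols = state.molecules
    att_idx = [[i for i, f in enumerate(m.features) if f.kind == "att_site"]
               for m in mols]
    for mi, mj in itertools.combinations_with_replacement(range(len(mols)), 2):
        intra = mi == mj
        pairs = (itertools.combinations(att_idx[mi], 2) if intra
                 else itertools.product(att_idx[mi], att_idx[mj]))
        for fi, fj in pairs:
            a = mols[mi].features[fi].att
            b = mols[mj].features[fj].att
            if frozenset((a.site_type, b.site_type)) != cond.active_type_pair:
                continue
            if a.channel != b.channel:
                if allow_mismatch:
                    events.append(CrossoverEvent(mi, fi, mj, fj, cond,
                                                 mismatched=True))
                continue
            if intra:
                if sites_compatible(a, b, cond).compatible:
                    events.append(CrossoverEvent(mi, fi, mj, fj, cond))
                    if a.channel.symmetric:
                        events.append(CrossoverEvent(mi, fi, mj, fj, cond,
                                                     alt_geometry=True))
            else:
                if a.channel.symmetric:
                    events.append(CrossoverEvent(mi, fi, mj, fj, cond))
                    events.append(CrossoverEvent(mi, fi, mj, fj, cond, flip_b=True))
                elif sites_compatible(a, b, cond).compatible:
                    events.append(CrossoverEvent(mi, fi, mj, fj, cond))
                else:  # same channel, opposed polarity: flip molecule b
                    events.append(CrossoverEvent(mi, fi, mj, fj, cond, flip_b=True))
    return events


def apply_event(state: ReactionState, event: CrossoverEvent,
                allow_mismatch: bool = False) -> ReactionState:
    """Successor state after one event."""
    mols = list(state.molecules)
    products = crossover(event, mols, allow_mismatch)
    consumed = {event.molecule_a, event.molecule_b}
    rest = [m for i, m in enumerate(mols) if i not in consumed]
    return ReactionState.make(rest + products, state.condition)


def react_to_closure(state: ReactionState, limits: ClosureLimits = ClosureLimits(),
                     allow_mismatch: bool = False) -> list[ReactionState]:
    """Breadth-first exploration of all event orders to terminal states.

    Terminal states (no event available) are returned deduplicated and in a
    deterministic order. Exceeding any limit raises
    :class:`~sira.errors.ClosureLimitError` carrying the partial terminal
    set, rather than silently truncating.
    """
    state = ReactionState.make(state.molecules, state.condition)
    seen = {state.key()}
    frontier = [state]
    terminal: dict[tuple, ReactionState] = {}
    depth = 0
    while frontier:
        if depth > limits.max_events:
            raise ClosureLimitError(
                f"closure exceeded max_events={limits.max_events}",
                partial=sorted(terminal.values(), key=lambda s: s.key()))
        nxt = []
        for st in frontier:
            events = enumerate_events(st, allow_mismatch)
            if not events:
                terminal.setdefault(st.key(), st)
                continue
            for ev in events:
                succ = apply_event(st, ev, allow_mismatch)
                if len(succ.molecules) > limits.max_molecules:
                    raise ClosureLimitError(
                        f"state exceeded max_molecules={limits.max_molecules}",
                        partial=sorted(terminal.values(), key=lambda s: s.key()))
                k = succ.key()
                if k not in seen:
                    seen.add(k)
                    if len(seen) > limits.max_states:
                        raise ClosureLimitError(
                            f"closure exceeded max_states={limits.max_states}",
                            partial=sorted(terminal.values(), key=lambda s: s.key()))
                    nxt.append(succ)
        frontier = nxt
        depth += 1
    return sorted(terminal.values(), key=lambda s: s.key())


# --------------------------------------------------------------------------
# product classification

def _has_ccdb(mol: DnaMolecule) -> bool:
    return any("ccdB".lower() in f.label.lower() for f in mol.features
               if f.kind in ("marker", "payload"))


def payload_cycle(mol: DnaMolecule) -> tuple[str, ...] | None:
    """Payload labels read 5'->3' along the payloads' common strand, or None
    if the payloads are not co-oriented."""
    pays = sorted((f for f in mol.features if f.kind == "payload"),
                  key=lambda f: f.start)
    if not pays:
        return ()
    strands = {f.strand for f in pays}
    if len(strands) != 1:
        return None
    labels = tuple(f.label for f in pays)
    return labels if strands == {"+"} else tuple(reversed(labels))


def _cyclic_equal(a: tuple, b: tuple) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    return any(b == a[i:] + a[:i] for i in range(len(a)))


def classify_products(terminal_states, scheme) -> dict:
    """Sort the circular molecules of terminal states into correct /
    misassembled / vector_reformed, per the selection logic of a SIRA
    reaction (ccdB counter-selection plus structure check).

    ``scheme`` provides the intended payload order via its parts
    (an :class:`~sira.design.AssemblyScheme`).
    """
    want = tuple(scheme.part_ids)
    seen = set()
    report = {"correct": [], "misassembled": [], "vector_reformed": []}
    for st in terminal_states:
        for m in st.molecules:
            if m.topology != "circular":
                continue
            k = identity_key(m)
            if k in seen:
                continue
            seen.add(k)
            if _has_ccdb(m):
                report["vector_reformed"].append(m)
                continue
            cyc = payload_cycle(m)
            if cyc is not None and (m.topology == "circular"
                                    and _cyclic_equal(cyc, want)):
                report["correct"].append(m)
            else:
                report["misassembled"].append(m)
    return report
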