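"""Planning ordered multi-fragment assemblies.

A SIRA vector carries two attB sites on different asymmetric channels
flanking a removable ccdB segment. Each of the n inserts ("cassettes") is
PCR-amplified with att tails so that consecutive cassettes share a channel
at their junction with opposed site types (attP against attB). With all
n+1 junction channels distinct, one pot of integrase joins the cassettes
end-to-end in a unique order and exchanges the array into the vector. One
integrase offers six asymmetric channels, so a single vector supports at
most five ordered fragments.

Conventions of this planner (the published diagrams fix the 3-fragment
channel assignments; the rest is a documented canonical extension):

* junction channels run TT, CT, GT, CA, CC, TC left to right, with the
  first and last equal to the vector's two channels;
* cassettes alternate attP-type and attB-type starting with attP; when n is
  even the final cassette is the single mixed attB/attP one;
* each cassette carries its two sites in inverted repeat (reducing
  primer-primer complementarity), which makes junction orientations
  alternate; the packaged vector has its second site reversed accordingly.
  When n is even the mixed final cassette carries parallel sites so the
  parity closes on the fixed vector.
"""

from __future__ import annotations

from dataclasses import dataclass

from .att import (
    DESIGN_OVERLAP_ORDER, ArmSet, AttSite, DEFAULT_ARMS, channel_of,
    find_att_sites, revcomp, sites_compatible, INT_ONLY,
)
from .errors import CapacityError, DesignError, ValidationError
from .molecules import DnaMolecule, Feature

MAX_FRAGMENTS = 5


@dataclass(frozen=True)
class Part:
    """A payload to be assembled, with an optional designed RBS that the
    forward PCR primer will prepend to it."""

    id: str
    payload: str
    rbs: str = ""

    def __post_init__(self):
        if not self.payload:
            raise ValidationError(f"part {self.id}: empty payload")
        object.__setattr__(self, "payload", self.payload.upper())
        object.__setattr__(self, "rbs", self.rbs.upper())
        bad = set(self.payload + self.rbs) - set("ACGT")
        if bad:
            raise ValidationError(f"part {self.id}: non-ACGT letters {sorted(bad)}")
        if self.rbs and find_att_sites(self.rbs):
            raise ValidationError(f"part {self.id}: rbs contains an att site")


@dataclass(frozen=True)
class AssemblyScheme:
    """Concrete site assignments for an ordered assembly.

    ``vector_sites`` are the vector's two attB sites as placed;
    ``position_sites[i]`` is the (left, right) pair of placed sites for
    cassette i+1; ``channel_order`` is the n+1 junction channels as design
    dinucleotides (stored-overlap spelling).
    """

    n: int
    part_ids: tuple[str, ...]
    vector_sites: tuple[AttSite, AttSite]
    position_sites: tuple[tuple[AttSite, AttSite], ...]
    channel_order: tuple[str, ...]
    arms: ArmSet = DEFAULT_ARMS

    def junction_pairs(self):
        """Per junction j = 0..n, the (upstream, downstream) placed sites."""
        out = []
        for j in range(self.n + 1):
            up = self.vector_sites[0] if j == 0 else self.position_sites[j - 1][1]
            down = self.vector_sites[1] if j == self.n else self.position_sites[j][0]
            out.append((up, down))
        return out

    def validate(self) -> None:
        if len(self.channel_order) != self.n + 1:
            raise DesignError("need n+1 junction channels")
        chans = [channel_of(c) for c in self.channel_order]
        if any(c.symmetric for c in chans):
            raise DesignError("junction channels must be asymmetric")
        if len(set(chans)) != len(chans):
            raise DesignError("junction channels must be pairwise distinct")
        for j, (up, down) in enumerate(self.junction_pairs()):
            if frozenset((up.site_type, down.site_type)) != frozenset("PB"):
                raise DesignError(f"junction {j}: need one attP and one attB")
            if not sites_compatible(up, down, INT_ONLY).compatible:
                raise DesignError(f"junction {j}: sites not compatible as placed")
            if up.channel != chans[j]:
                raise DesignError(f"junction {j}: channel disagrees with channel_order")


@dataclass(frozen=True)
class PrimerPair:
    """Tailed primers for one cassette. Both strings read 5'->3'."""

    forward: str
    reverse: str
    annealing_length: int


def vector_att_pair(vector: DnaMolecule) -> tuple[Feature, Feature]:
    """The vector's two exchange-competent (attP/attB) features, ordered so
    the removable (ccdB) segment lies between the first site's end and the
    second site's start walking forward on the top strand. Hybrid attL/attR
    sites elsewhere on the molecule (inert in an integrase-alone reaction)
    are ignored."""
    sites = [f for f in vector.att_features() if f.att.site_type in "PB"]
    if len(sites) != 2:
        raise DesignError(f"vector {vector.id}: need exactly 2 attP/attB sites, "
                          f"found {len(sites)}")
    s1, s2 = sorted(sites, key=lambda f: f.start)
    ccdb = [f for f in vector.features
            if f.kind in ("marker", "payload") and "ccdb" in f.label.lower()]
    if ccdb and not (s1.end <= ccdb[0].start and ccdb[0].end <= s2.start):
        s1, s2 = s2, s1  # ccdB sits in the wrapped span
    return s1, s2


def _alternating_orientations(o_first: str, o_last: str, n: int) -> list[str]:
    flip = {"forward": "reverse", "reverse": "forward"}
    out = [o_first]
    for _ in range(n - 1):
        out.append(flip[out[-1]])
    out.append(o_last)
    return out


def plan_assembly(parts, vector: DnaMolecule, site_set=None,
                  arms: ArmSet = DEFAULT_ARMS) -> AssemblyScheme:
    """Assign per-position att sites for an ordered assembly of ``parts``
    into ``vector``.

    ``site_set`` optionally overrides the junction channel order: a list of
    n+1 design dinucleotides whose first and last must match the vector's
    channels.
    """
    parts = list(parts)
    n = len(parts)
    if n < 1:
        raise DesignError("need at least one part")
    if n > MAX_FRAGMENTS:
        raise CapacityError(
            f"{n} fragments need {n + 1} distinct asymmetric channels; a single "
            f"integrase provides only {len(DESIGN_OVERLAP_ORDER)} (max "
            f"{MAX_FRAGMENTS} fragments)")
    if len({p.id for p in parts}) != n:
        raise DesignError("part ids must be unique")

    f1, f2 = vector_att_pair(vector)
    vec_type = f1.att.site_type
    if vec_type not in "PB" or f2.att.site_type != vec_type:
        raise DesignError(
            f"vector {vector.id}: needs two attB (or two attP) sites, found "
            f"{f1.att.label()}/{f2.att.label()}")
    for f in (f1, f2):
        if f.att.channel.symmetric:
            raise DesignError(
                f"vector {vector.id}: site {f.att.label()} uses a symmetric channel, "
                "which cannot enforce a defined orientation")
    cv1, cv2 = f1.att.overlap, f2.att.overlap
    if f1.att.channel == f2.att.channel:
        raise DesignError("vector sites must use two different channels")
    cassette_first = "P" if vec_type == "B" else "B"

    if site_set is not None:
        channels = [c.upper() for c in site_set]
        if len(channels) != n + 1:
            raise DesignError(f"site_set must list {n + 1} junction channels")
        if channels[0] != cv1 or channels[-1] != cv2:
            raise DesignError("site_set must start and end with the vector channels")
    else:
        interior = [c for c in DESIGN_OVERLAP_ORDER
                    if channel_of(c) not in (f1.att.channel, f2.att.channel)]
        if n - 1 > len(interior):
            raise CapacityError("not enough free channels for interior junctions")
        channels = [cv1] + interior[: n - 1] + [cv2]
    chan_objs = [channel_of(c) for c in channels]
    if any(c.symmetric for c in chan_objs) or len(set(chan_objs)) != n + 1:
        raise DesignError("junction channels must be distinct and asymmetric")

    orients = _alternating_orientations(f1.att.orientation, f2.att.orientation, n)
    other = {"P": "B", "B": "P"}
    position_sites = []
    for i in range(1, n + 1):
        left_type = cassette_first if i % 2 == 1 else other[cassette_first]
        right_type = left_type if i < n else cassette_first
        left = AttSite.make(left_type, channels[i - 1], orients[i - 1], arms)
        right = AttSite.make(right_type, channels[i], orients[i], arms)
        position_sites.append((left, right))

    scheme = AssemblyScheme(
        n=n,
        part_ids=tuple(p.id for p in parts),
        vector_sites=(f1.att, f2.att),
        position_sites=tuple(position_sites),
        channel_order=tuple(channels),
        arms=arms,
    )
    scheme.validate()
    return scheme


def build_cassette(part: Part, position_spec: tuple[AttSite, AttSite],
                   mol_id: str | None = None) -> DnaMolecule:
    """The linear amplicon a designed primer pair produces from a part:
    placed left site + RBS + payload + placed right site, annotated."""
    left, right = position_spec
    lseq, rseq = left.placed_sequence, right.placed_sequence
    seq = lseq + part.rbs + part.payload + rseq
    feats = [Feature("att_site", 0, len(lseq),
                     "+" if left.orientation == "forward" else "-",
                     left.label(), left)]
    pos = len(lseq)
    if part.rbs:
        feats.append(Feature("rbs", pos, pos + len(part.rbs), "+", f"{part.id}.rbs"))
        pos += len(part.rbs)
    feats.append(Feature("payload", pos, pos + len(part.payload), "+", part.id))
    pos += len(part.payload)
    feats.append(Feature("att_site", pos, pos + len(rseq),
                         "+" if right.orientation == "forward" else "-",
                         right.label(), right))
    return DnaMolecule(mol_id or f"cassette_{part.id}", seq, "linear", feats)


def design_primers(part: Part, position_spec: tuple[AttSite, AttSite],
                   annealing_length: int = 20) -> PrimerPair:
    """Tailed primer pair whose amplicon is :func:`build_cassette`'s
    sequence: att tails reconstruct the placed sites, the RBS rides on the
    forward tail, and the annealing regions are the payload termini."""
    if len(part.payload) < annealing_length:
        raise DesignError(
            f"part {part.id}: payload ({len(part.payload)} nt) shorter than "
            f"annealing length {annealing_length}")
    left, right = position_spec
    fwd = left.placed_sequence + part.rbs + part.payload[:annealing_length]
    rev = revcomp(right.placed_sequence) + revcomp(part.payload[-annealing_length:])
    return PrimerPair(fwd, rev, annealing_length)


def amplicon_of(part: Part, position_spec: tuple[AttSite, AttSite],
                primers: PrimerPair) -> str:
    """String-level PCR: apply a tailed primer pair to the payload template."""
    template = part.payload
    if not template.startswith(primers.forward[-primers.annealing_length:]):
        raise DesignError("forward primer does not anneal to the payload 5' end")
    if not revcomp(primers.reverse[-primers.annealing_length:]) == \
            template[-primers.annealing_length:]:
        raise DesignError("reverse primer does not anneal to the payload 3' end")
    return (primers.forward[:-primers.annealing_length] + template
            + revcomp(primers.reverse[:-primers.annealing_length]))


def junction_product_site(upstream: AttSite, downstream: AttSite) -> tuple[AttSite, str]:
    """The hybrid site left in the plasmid where the upstream half of one
    placed site joins the downstream half of another, with its feature
    strand. attP x attB junctions give attL; attL x attR junctions give
    attB or attP depending on placement (this is what makes the two-step
    edit leave a cassette flanked by two attB sites)."""
    from .engine import _junction
    return _junction(upstream, downstream)


def predict_assembly(scheme: AssemblyScheme, parts, vector: DnaMolecule
                     ) -> DnaMolecule:
    """Direct string construction of the expected circular product, without
    running the reaction engine: n+1 hybrid junctions (attL sites for a
    standard attB vector), payloads in order, vector backbone closing the
    circle.

    By construction this equals (normalize-identity) the unique correct
    product of closing the reaction on the same inputs.
    """
    parts = list(parts)
    scheme.validate()
    if tuple(p.id for p in parts) != scheme.part_ids:
        raise DesignError("parts do not match the scheme's part order")
    if vector.topology != "circular":
        raise DesignError("vector must be circular")
    f1, f2 = vector_att_pair(vector)
    i1 = vector.features.index(f1)
    i2 = vector.features.index(f2)
    # Frame the vector with its first site at the origin.
    framed = vector.rotated(f1.start)
    s2 = framed.features[i2]
    consumed = {i1, i2}
    backbone_seq = framed.sequence[s2.end:]
    backbone_feats = [f for i, f in enumerate(framed.features)
                      if i not in consumed and not f.wraps
                      and s2.end <= f.start and f.end <= len(framed)]

    pairs = scheme.junction_pairs()
    seq_parts: list[str] = []
    feats: list[Feature] = []
    pos = 0

    def emit_junction(j: int):
        nonlocal pos
        up, down = pairs[j]
        jsite, strand = junction_product_site(up, down)
        jseq = jsite.placed_sequence
        feats.append(Feature("att_site", pos, pos + len(jseq), strand,
                             jsite.label(), jsite))
        seq_parts.append(jseq)
        pos += len(jseq)

    for i, part in enumerate(parts):
        emit_junction(i)
        if part.rbs:
            feats.append(Feature("rbs", pos, pos + len(part.rbs), "+", f"{part.id}.rbs"))
            seq_parts.append(part.rbs)
            pos += len(part.rbs)
        feats.append(Feature("payload", pos, pos + len(part.payload), "+", part.id))
        seq_parts.append(part.payload)
        pos += len(part.payload)
    emit_junction(scheme.n)
    for f in backbone_feats:
        feats.append(Feature(f.kind, f.start - s2.end + pos, f.end - s2.end + pos,
                             f.strand, f.label, f.att))
    seq_parts.append(backbone_seq)
    name = "assembly_" + "-".join(scheme.part_ids)
    return DnaMolecule(name, "".join(seq_parts), "circular",
                       sorted(feats, key=lambda f: f.start))


# kept importable for callers that only need the length check
def scheme_capacity_ok(n: int) -> bool:
    return 1 <= n <= MAX_FRAGMENTS
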