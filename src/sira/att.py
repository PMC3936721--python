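"""The algebra of serine-integrase att sites.

A ϕC31-type integrase recombines a ~46 bp *attP* site with a ~46 bp *attB*
site. Each site is cut with a two-nucleotide stagger around a central 2 bp
"overlap"; the half-sites are exchanged and rejoined, producing the hybrid
sites *attL* and *attR*. Two sites recombine only when their overlaps match,
and the overlap also sets the left/right polarity of the site: a site placed
in reverse orientation presents the reverse complement of its stored overlap
to the top strand. Overlaps therefore group into reverse-complement
equivalence classes ("channels"); sites from different channels never
recombine, which is what makes one-pot multi-junction assembly possible.
There are 6 asymmetric channels (usable for ordered assembly) and 4
symmetric, self-complementary ones (which recombine in both relative
orientations and are avoided in ordered designs).

Directionality: with integrase alone only attP x attB recombines; adding the
recombination directionality factor (RDF, ϕC31 gp3) switches specificity to
attL x attR and shuts off attP x attB.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .errors import IncompatibleSitesError, ValidationError

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: Conventional listing order of the six asymmetric design overlaps
#: (top-strand dinucleotide naming each orthogonal attP/attB pair).
DESIGN_OVERLAP_ORDER = ("TT", "CT", "GT", "CA", "CC", "TC")

SITE_TYPES = ("P", "B", "L", "R")

#: Arm origin (P-arm vs B-arm) of the left and right half of each site type.
#: attL = B-arm | overlap | P-arm and attR = P-arm | overlap | B-arm — the
#: standard serine-integrase B-P' / P-B' convention. Kept as one constant so
#: the convention could be flipped in a single place.
HALF_SITE_ORIGIN = {
    "P": ("P", "P"),
    "B": ("B", "B"),
    "L": ("B", "P"),
    "R": ("P", "B"),
}

#: Site type produced when a junction joins a left half of one origin to a
#: right half of another.
JUNCTION_TYPE = {
    ("B", "P"): "L",
    ("P", "B"): "R",
    ("P", "P"): "P",
    ("B", "B"): "B",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_dna(seq: str, what: str) -> str:
    s = seq.upper()
    if not s or set(s) - set("ACGT"):
        raise ValidationError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")
    return s


def validate_overlap(overlap: str) -> str:
    """Validate and canonicalize (uppercase) a 2 nt overlap dinucleotide."""
    if not isinstance(overlap, str) or len(overlap) != 2:
        raise ValidationError(f"overlap must be a 2 nt DNA string, got {overlap!r}")
    return _validate_dna(overlap, "overlap")


@dataclass(frozen=True, order=True)
class OverlapChannel:
    """Reverse-complement equivalence class of 2 bp overlaps.

    ``representative`` is the lexicographically smaller of the dinucleotide
    and its reverse complement; ``symmetric`` is True for self-complementary
    overlaps (AT, CG, GC, TA), which impose no relative orientation on the
    recombining sites.
    """

    representative: str
    symmetric: bool = field(compare=False)

    @property
    def members(self) -> tuple[str, ...]:
        rc = revcomp(self.representative)
        return (self.representative,) if self.symmetric else (self.representative, rc)

    @property
    def name(self) -> str:
        """Human-readable name, e.g. ``"AA/TT"`` or ``"TA"``."""
        return "/".join(self.members)


def channel_of(overlap: str) -> OverlapChannel:
    """Map a 2 nt overlap to its orthogonality channel.

    ``channel_of(d) == channel_of(revcomp(d))`` for every dinucleotide d.
    """
    d = validate_overlap(overlap)
    rc = revcomp(d)
    return OverlapChannel(representative=min(d, rc), symmetric=(d == rc))


def enumerate_channels() -> list[OverlapChannel]:
    """All 10 channels over the 16 dinucleotides.

    Order: the 6 asymmetric channels in :data:`DESIGN_OVERLAP_ORDER`
    (TT, CT, GT, CA, CC, TC), then the 4 symmetric channels alphabetically.
    """
    asym = [channel_of(d) for d in DESIGN_OVERLAP_ORDER]
    sym = sorted(
        {channel_of("".join(p)) for p in itertools.product("ACGT", repeat=2)
         if channel_of("".join(p)).symmetric}
    )
    return asym + sym


@dataclass(frozen=True)
class ArmSet:
    """The invariant arm sequences of one integrase's att sites.

    The packaged defaults are distinct placeholder 22-mers giving a 46 bp
    full site; users working with the real ϕC31 arms substitute them here.
    All site logic is arm-agnostic.
    """

    p_left: str
    p_right: str
    b_left: str
    b_right: str

    def __post_init__(self):
        for name in ("p_left", "p_right", "b_left", "b_right"):
            object.__setattr__(self, name, _validate_dna(getattr(self, name), name))

    def arm(self, origin: str, side: int) -> str:
        """Arm sequence for origin 'P'/'B' and side 0 (left) / 1 (right)."""
        return {
            ("P", 0): self.p_left, ("P", 1): self.p_right,
            ("B", 0): self.b_left, ("B", 1): self.b_right,
        }[(origin, side)]


#: Placeholder arms (22 nt each -> 46 bp sites). Arbitrary fixed sequences,
#: chosen pairwise distinct; not the natural ϕC31 arm sequences.
DEFAULT_ARMS = ArmSet(
    p_left="GTGCCAGGGCGTGCCCTTGGGC",
    p_right="CCCAACTGGGGTAACCTTTGAG",
    b_left="CGGTGCGGGTGCCAGGGCGTGC",
    b_right="TTGAGCCTGGGGACTTCTGAGC",
)


@dataclass(frozen=True)
class EnzymeCondition:
    """Which proteins are present. Integrase is required for any event;
    the RDF redirects specificity from attP x attB to attL x attR."""

    integrase_present: bool = True
    rdf_present: bool = False

    def __post_init__(self):
        if self.rdf_present and not self.integrase_present:
            raise ValidationError("RDF without integrase catalyses nothing")

    @property
    def active_type_pair(self) -> frozenset[str]:
        """The unordered site-type pair this condition recombines."""
        return frozenset("LR") if self.rdf_present else frozenset("PB")


INT_ONLY = EnzymeCondition(integrase_present=True, rdf_present=False)
INT_RDF = EnzymeCondition(integrase_present=True, rdf_present=True)


@dataclass(frozen=True)
class AttSite:
    """A typed, oriented recombination site.

    ``overlap``, ``left_arm`` and ``right_arm`` are stored in the site's own
    forward frame; the full forward-frame sequence is
    ``left_arm + overlap + right_arm``. ``orientation`` says how the site
    lies on its host molecule's top strand; all reverse-orientation
    reasoning goes through :meth:`effective_overlap`.
    """

    site_type: str
    overlap: str
    left_arm: str
    right_arm: str
    orientation: str = "forward"

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise ValidationError(f"site_type must be one of {SITE_TYPES}, got {self.site_type!r}")
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(f"orientation must be forward/reverse, got {self.orientation!r}")
        object.__setattr__(self, "overlap", validate_overlap(self.overlap))
        object.__setattr__(self, "left_arm", _validate_dna(self.left_arm, "left_arm"))
        object.__setattr__(self, "right_arm", _validate_dna(self.right_arm, "right_arm"))

    @classmethod
    def make(cls, site_type: str, overlap: str, orientation: str = "forward",
             arms: ArmSet = DEFAULT_ARMS) -> "AttSite":
        """Build a site with arms drawn from an :class:`ArmSet` by type."""
        if site_type not in SITE_TYPES:
            raise ValidationError(f"site_type must be one of {SITE_TYPES}, got {site_type!r}")
        lo, ro = HALF_SITE_ORIGIN[site_type]
        return cls(site_type, overlap, arms.arm(lo, 0), arms.arm(ro, 1), orientation)

    @property
    def sequence(self) -> str:
        """Forward-frame site sequence."""
        return self.left_arm + self.overlap + self.right_arm

    @property
    def placed_sequence(self) -> str:
        """Sequence as it appears on the host molecule's top strand."""
        return self.sequence if self.orientation == "forward" else revcomp(self.sequence)

    def effective_overlap(self) -> str:
        """Overlap presented to the top strand in the placed orientation."""
        return self.overlap if self.orientation == "forward" else revcomp(self.overlap)

    @property
    def channel(self) -> OverlapChannel:
        return channel_of(self.overlap)

    def flipped(self) -> "AttSite":
        """The same site placed in the opposite orientation."""
        return replace(self, orientation="reverse" if self.orientation == "forward" else "forward")

    def label(self) -> str:
        """Conventional name, e.g. ``attP^TT``."""
        return f"att{self.site_type}^{self.overlap}"


@dataclass(frozen=True)
class CompatReport:
    """Result of a pairwise compatibility check."""

    compatible: bool
    relative_orientation: str | None = None  # parallel | antiparallel | both
    reason: str | None = None


def sites_compatible(a: AttSite, b: AttSite, cond: EnzymeCondition = INT_ONLY) -> CompatReport:
    """Can two placed sites recombine under the given enzyme condition?

    Compatible iff (i) the unordered type pair is {P,B} without RDF or {L,R}
    with RDF, and (ii) the effective overlaps (reverse-complemented for
    reverse-orientation sites) are equal. Sites on a symmetric channel match
    in both relative orientations, reported as ``both``.
    """
    if not cond.integrase_present:
        return CompatReport(False, reason="no integrase present")
    if frozenset((a.site_type, b.site_type)) != cond.active_type_pair:
        want = "x".join(sorted(cond.active_type_pair))
        return CompatReport(False, reason=f"type pair {a.site_type}x{b.site_type} inactive ({want} required)")
    if a.channel != b.channel:
        return CompatReport(False, reason=f"orthogonal channels {a.channel.name} vs {b.channel.name}")
    if a.channel.symmetric:
        return CompatReport(True, relative_orientation="both")
    if a.effective_overlap() != b.effective_overlap():
        return CompatReport(False, reason="effective overlaps are reverse complements (opposed polarity)")
    rel = "parallel" if a.orientation == b.orientation else "antiparallel"
    return CompatReport(True, relative_orientation=rel)


def junction_site(upstream: AttSite, downstream: AttSite) -> AttSite:
    """Site formed by joining the left half of ``upstream`` (in its own
    frame, through the overlap) to the right half of ``downstream``.

    attP x attB junctions give attL or attR; attL x attR junctions give back
    attP or attB. The overlap written into the junction is the upstream
    site's (they are equal for matched recombination)."""
    lo = HALF_SITE_ORIGIN[upstream.site_type][0]
    ro = HALF_SITE_ORIGIN[downstream.site_type][1]
    jtype = JUNCTION_TYPE[(lo, ro)]
    return AttSite(jtype, upstream.overlap, upstream.left_arm, downstream.right_arm, "forward")


def hybrid_sites(p: AttSite, b: AttSite) -> tuple[AttSite, AttSite]:
    """Hybrid sites from one recombination event, in the frame of ``p``.

    For an attP x attB pair (compatible with integrase alone) returns
    ``(attL, attR)`` with attL = b.left_arm|overlap|p.right_arm and
    attR = p.left_arm|overlap|b.right_arm. For an attL x attR pair
    (compatible with integrase + RDF) returns ``(attP, attB)`` — the exact
    reversal, so hybrids of hybrids reproduce the original pair.

    Each product carries the stored overlap of the site contributing its
    left half; for a same-orientation pair these are identical, while for an
    antiparallel pair (e.g. forward attP^TT x reversed attB^AA) the two
    hybrids carry the two reverse-complement spellings of the shared duplex.
    """
    types = frozenset((p.site_type, b.site_type))
    cond = INT_ONLY if types == frozenset("PB") else INT_RDF
    rep = sites_compatible(p, b, cond)
    if not rep.compatible:
        raise IncompatibleSitesError(
            f"{p.label()} ({p.orientation}) x {b.label()} ({b.orientation}): {rep.reason}")
    first = junction_site(b, p)   # b-left | ov | p-right  -> attL (or attP)
    second = junction_site(p, b)  # p-left | ov | b-right  -> attR (or attB)
    return first, second


def find_att_sites(seq: str, arms: ArmSet = DEFAULT_ARMS) -> list[dict]:
    """Detect att sites in a raw sequence by their arm signatures.

    Scans both strands for left_arm + NN + right_arm of each site type and
    returns dicts with keys site_type, overlap (forward frame), orientation,
    start, end (0-based half-open on the given strand's top). Used to verify
    designed amplicons and to annotate plain FASTA inputs.
    """
    seq = seq.upper()
    hits = []
    for site_type in SITE_TYPES:
        lo, ro = HALF_SITE_ORIGIN[site_type]
        left, right = arms.arm(lo, 0), arms.arm(ro, 1)
        for orientation, l_pat, r_pat in (
            ("forward", left, right),
            ("reverse", revcomp(right), revcomp(left)),
        ):
            start = 0
            while True:
                i = seq.find(l_pat, start)
                if i < 0:
                    break
                j = i + len(l_pat)
                if seq[j + 2: j + 2 + len(r_pat)] == r_pat:
                    ov = seq[j: j + 2]
                    if orientation == "reverse":
                        ov = revcomp(ov)
                    hits.append({
                        "site_type": site_type,
                        "overlap": ov,
                        "orientation": orientation,
                        "start": i,
                        "end": j + 2 + len(r_pat),
                    })
                start = i + 1
    hits.sort(key=lambda h: (h["start"], h["site_type"]))
    return hits


def site_from_config(cfg: dict, arms: ArmSet = DEFAULT_ARMS) -> AttSite:
    """Build a site from a small config mapping.

    Recognized keys: ``site_type`` (required), ``overlap`` (required),
    ``orientation`` (default forward), and optional custom ``left_arm`` /
    ``right_arm`` overriding the arm set.
    """
    try:
        site_type = cfg["site_type"]
        overlap = cfg["overlap"]
    except KeyError as exc:
        raise ValidationError(f"site config missing required key {exc}") from exc
    orientation = cfg.get("orientation", "forward")
    base = AttSite.make(site_type, overlap, orientation, arms)
    if "left_arm" in cfg or "right_arm" in cfg:
        base = replace(
            base,
            left_arm=cfg.get("left_arm", base.left_arm),
            right_arm=cfg.get("right_arm", base.right_arm),
        )
    return base
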