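"""Deterministic toy fixtures: a pSIRA1-like vector, parts, and a prebuilt
assembly, so every workflow can run with no external data.

The vector mimics the published layout: two attB sites on the TT and TC
channels (the second in reverse orientation, matching the inverted-repeat
convention of the planner) flanking a removable ccdB placeholder, with an
AmpR placeholder on the backbone. Payloads are random sequences — real
coding sequences and codon content are deliberately not emulated; the
recombination logic only sees att sites and intervals.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .att import ArmSet, AttSite, DEFAULT_ARMS
from .design import Part, plan_assembly, predict_assembly
from .errors import ValidationError
from .molecules import DnaMolecule, Feature


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic fixture set. The same spec always
    produces byte-identical molecules."""

    seed: int = 1
    n_parts: int = 3
    payload_length_range: tuple[int, int] = (60, 120)
    vector_backbone_length: int = 300
    include_ccdb: bool = True
    include_cmr: bool = False
    include_kanr: bool = False
    part_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        lo, hi = self.payload_length_range
        if lo <= 0 or hi < lo or self.vector_backbone_length <= 0:
            raise ValidationError("fixture lengths must be positive and ordered")
        if self.n_parts < 1:
            raise ValidationError("need at least one part")
        if self.part_labels is not None and len(self.part_labels) != self.n_parts:
            raise ValidationError("part_labels must match n_parts")


@dataclass(frozen=True)
class FixtureSet:
    vector: DnaMolecule
    parts: tuple[Part, ...]
    scheme: object
    prebuilt_assembly: DnaMolecule


def _random_seq(rng: random.Random, n: int, forbidden: tuple[str, ...]) -> str:
    """Random ACGT sequence avoiding any forbidden substring (site arms),
    so sequence-level site detection cannot produce spurious hits."""
    for _ in range(100):
        s = "".join(rng.choice("ACGT") for _ in range(n))
        if not any(w in s for w in forbidden):
            return s
    raise ValidationError("could not draw a sequence avoiding the site arms")


def _arm_words(arms: ArmSet) -> tuple[str, ...]:
    from .att import revcomp
    words = (arms.p_left, arms.p_right, arms.b_left, arms.b_right)
    return words + tuple(revcomp(w) for w in words)


def make_vector(rng: random.Random, spec: FixtureSpec,
                arms: ArmSet = DEFAULT_ARMS) -> DnaMolecule:
    """Circular pSIRA1-like vector: attB^TT (forward) ... removable ccdB
    segment ... attB^TC (reverse) ... backbone."""
    forbidden = _arm_words(arms)
    b1 = AttSite.make("B", "TT", "forward", arms)
    b2 = AttSite.make("B", "TC", "reverse", arms)
    feats: list[Feature] = []
    pieces: list[str] = []
    pos = 0

    def emit(seq: str, kind: str | None = None, label: str = "", strand: str = "+",
             att: AttSite | None = None):
        nonlocal pos
        if kind:
            feats.append(Feature(kind, pos, pos + len(seq), strand, label, att))
        pieces.append(seq)
        pos += len(seq)

    emit(b1.placed_sequence, "att_site", b1.label(), "+", b1)
    emit(_random_seq(rng, 12, forbidden))
    if spec.include_ccdb:
        emit(_random_seq(rng, 84, forbidden), "marker", "ccdB")
    if spec.include_cmr:
        emit(_random_seq(rng, 66, forbidden), "marker", "CmR")
    emit(_random_seq(rng, 12, forbidden))
    emit(b2.placed_sequence, "att_site", b2.label(), "-", b2)
    backbone = _random_seq(rng, spec.vector_backbone_length, forbidden)
    start = pos
    pieces.append(backbone)
    feats.append(Feature("marker", start + 20, start + 20 + 90, "+", "AmpR"))
    if spec.include_kanr:
        feats.append(Feature("marker", start + 130, start + 130 + 90, "+", "KanR"))
    return DnaMolecule("pSIRA-toy", "".join(pieces), "circular",
                       sorted(feats, key=lambda f: f.start))


def make_parts(rng: random.Random, spec: FixtureSpec,
               arms: ArmSet = DEFAULT_ARMS) -> tuple[Part, ...]:
    forbidden = _arm_words(arms)
    lo, hi = spec.payload_length_range
    labels = spec.part_labels or tuple(f"gene{i + 1}" for i in range(spec.n_parts))
    parts = []
    for label in labels:
        payload = _random_seq(rng, rng.randint(lo, hi), forbidden)
        rbs = "TAAGGAGG" + _random_seq(rng, 4, forbidden)
        parts.append(Part(label, payload, rbs))
    return tuple(parts)


def generate_fixtures(spec: FixtureSpec = FixtureSpec(),
                      arms: ArmSet = DEFAULT_ARMS) -> FixtureSet:
    """Vector + parts + scheme + predicted assembly, all deterministic in
    ``spec.seed``."""
    rng = random.Random(spec.seed)
    vector = make_vector(rng, spec, arms)
    parts = make_parts(rng, spec, arms)
    scheme = plan_assembly(parts, vector, arms=arms)
    assembly = predict_assembly(scheme, parts, vector)
    return FixtureSet(vector=vector, parts=parts, scheme=scheme,
                      prebuilt_assembly=assembly)
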