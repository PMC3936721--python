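"""Linear/circular DNA molecules with positioned features.

Coordinates are 0-based half-open on the top strand. On circular molecules a
feature may span the origin; it is stored as ``(start, end)`` with
``end <= start`` meaning it wraps. The origin of a circle carries no meaning:
all identity comparisons go through :func:`normalize`, which rotates/flips a
molecule to a canonical frame (lexicographically smallest sequence over all
rotations of both strands).

GenBank and FASTA I/O go through Biopython. att sites are serialized as
``misc_recomb`` features with qualifiers ``site_type``, ``overlap``,
``channel``, ``orientation`` (plus the arm sequences, so a round trip is
exact); other feature kinds map onto conventional GenBank keys.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .att import AttSite, channel_of, find_att_sites, revcomp
from .errors import ValidationError

FEATURE_KINDS = ("att_site", "payload", "rbs", "promoter", "marker")

# GenBank feature key used for each kind (and back).
_KIND_TO_KEY = {
    "att_site": "misc_recomb",
    "payload": "CDS",
    "rbs": "RBS",
    "promoter": "promoter",
    "marker": "misc_feature",
}
_KEY_TO_KIND = {v: k for k, v in _KIND_TO_KEY.items()}


@dataclass(frozen=True)
class Feature:
    """A positioned annotation. ``att`` is present iff kind == 'att_site'."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""
    att: AttSite | None = None

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if (self.att is not None) != (self.kind == "att_site"):
            raise ValidationError("att payload present iff kind == 'att_site'")
        if self.att is not None:
            want = "forward" if self.strand == "+" else "reverse"
            if self.att.orientation != want:
                raise ValidationError(
                    f"att orientation {self.att.orientation} disagrees with strand {self.strand}")

    @property
    def wraps(self) -> bool:
        return self.end <= self.start

    def length(self, mol_length: int) -> int:
        return self.end - self.start if not self.wraps else mol_length - self.start + self.end

    def signature(self) -> tuple:
        """Position-independent identity used in normalized comparisons."""
        att_sig = None
        if self.att is not None:
            att_sig = (self.att.site_type, self.att.overlap,
                       self.att.left_arm, self.att.right_arm)
        return (self.kind, self.label, self.strand, att_sig)


@dataclass
class DnaMolecule:
    """A linear or circular double-stranded DNA, represented by its top
    strand, with a list of positioned features."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        bad = sorted(set(self.sequence) - set("ACGTRYSWKMBDHVN"))
        if bad:
            raise ValidationError(f"molecule {self.id}: non-IUPAC letters {bad}")
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"topology must be linear/circular, got {self.topology!r}")
        L = len(self.sequence)
        for f in self.features:
            if not (0 <= f.start < L and 0 < f.end <= L):
                raise ValidationError(
                    f"molecule {self.id}: feature {f.label!r} interval ({f.start},{f.end}) "
                    f"outside [0,{L})")
            if f.wraps and self.topology == "linear":
                raise ValidationError(
                    f"molecule {self.id}: wrapped feature {f.label!r} on a linear molecule")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- feature access ----------------------------------------------------

    def feature_sequence(self, f: Feature) -> str:
        """The feature's sequence in its own strand frame."""
        raw = (self.sequence[f.start:f.end] if not f.wraps
               else self.sequence[f.start:] + self.sequence[:f.end])
        return raw if f.strand == "+" else revcomp(raw)

    def att_features(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "att_site"]

    def payload_labels(self) -> list[str]:
        """Payload labels in top-strand positional order."""
        pays = [f for f in self.features if f.kind == "payload"]
        return [f.label for f in sorted(pays, key=lambda f: f.start)]

    # -- frame changes -----------------------------------------------------

    def reverse_complement(self) -> "DnaMolecule":
        L = len(self.sequence)
        feats = []
        for f in self.features:
            ns, ne = (L - f.end) % L, L - f.start
            att = f.att.flipped() if f.att is not None else None
            feats.append(Feature(f.kind, ns, ne, "-" if f.strand == "+" else "+", f.label, att))
        return DnaMolecule(self.id, revcomp(self.sequence), self.topology, feats)

    def rotated(self, k: int) -> "DnaMolecule":
        """Circular only: new origin at position k of the current frame.

        Features crossing the new origin become wrapped features.
        """
        if self.topology != "circular":
            raise ValidationError("only circular molecules can be rotated")
        L = len(self.sequence)
        k %= L
        seq = self.sequence[k:] + self.sequence[:k]
        feats = []
        for f in self.features:
            ln = f.length(L)
            ns = (f.start - k) % L
            ne = ns + ln
            if ne > L:
                ne -= L
            feats.append(replace(f, start=ns, end=ne))
        return DnaMolecule(self.id, seq, self.topology, feats)


# -- canonical form --------------------------------------------------------

def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    n = len(s)
    ss = s + s
    fail = [-1] * (2 * n)
    k = 0
    for j in range(1, 2 * n):
        i = fail[j - k - 1]
        while i != -1 and ss[j] != ss[k + i + 1]:
            if ss[j] < ss[k + i + 1]:
                k = j - i - 1
            i = fail[i]
        if ss[j] != ss[k + i + 1]:
            if ss[j] < ss[k]:
                k = j
            fail[j - k] = -1
        else:
            fail[j - k] = i + 1
    return k


def normalize(m: DnaMolecule) -> DnaMolecule:
    """Canonical frame of a molecule; idempotent.

    Linear: the smaller of the sequence and its reverse complement (ties keep
    the current strand). Circular: the lexicographically smallest rotation
    over both strands; among equal-sequence candidates the one with the
    smallest feature tuple wins, so the result is fully deterministic.
    """
    if m.topology == "linear":
        rc = revcomp(m.sequence)
        return m if m.sequence <= rc else m.reverse_complement()
    candidates = []
    for strand_mol in (m, m.reverse_complement()):
        k = _least_rotation(strand_mol.sequence)
        candidates.append(strand_mol.rotated(k))
    best_seq = min(c.sequence for c in candidates)
    pool = [c for c in candidates if c.sequence == best_seq]
    if len(pool) > 1:
        pool.sort(key=_feature_tuple)
    best = pool[0]
    # A rotationally periodic sequence can have several least rotations on
    # one strand; resolve by trying every rotation that reproduces best_seq.
    n = len(best.sequence)
    if n and best.sequence in (best.sequence + best.sequence)[1:-1]:
        alts = []
        for strand_mol in (m, m.reverse_complement()):
            doubled = strand_mol.sequence + strand_mol.sequence
            for k in range(n):
                if doubled[k:k + n] == best_seq:
                    alts.append(strand_mol.rotated(k))
        alts.sort(key=_feature_tuple)
        best = alts[0]
    return best


def _feature_tuple(m: DnaMolecule) -> tuple:
    return tuple(sorted((f.start, f.end, f.signature()) for f in m.features))


def identity_key(m: DnaMolecule) -> tuple:
    """Hashable identity of a molecule under normalize-equality: topology,
    canonical sequence, and the multiset of positioned feature signatures."""
    n = normalize(m)
    return (n.topology, n.sequence, _feature_tuple(n))


def total_base_count(molecules) -> Counter:
    """Summed top-strand base counts over a collection of molecules."""
    total: Counter = Counter()
    for m in molecules:
        total.update(m.sequence)
    return total


def duplex_base_count(molecules) -> Counter:
    """Summed base counts over both strands.

    This is the quantity conserved exactly by every crossover: a free
    molecule carries no intrinsic strand, and events that pair opposed-
    polarity sites read one participant on its bottom strand, so top-strand
    counts alone can swap A<->T / C<->G while the duplex content is
    untouched.
    """
    total: Counter = Counter()
    for m in molecules:
        total.update(m.sequence)
        total.update(revcomp(m.sequence))
    return total


# -- annotation ------------------------------------------------------------

def annotate_att_sites(m: DnaMolecule, arms=None) -> DnaMolecule:
    """Return a copy of ``m`` with att_site features detected from sequence.

    Existing att_site features are replaced; other features are kept. Only
    non-wrapped occurrences are found on circular molecules (rotate first if
    a site might span the origin).
    """
    from .att import DEFAULT_ARMS
    arms = arms or DEFAULT_ARMS
    feats = [f for f in m.features if f.kind != "att_site"]
    for hit in find_att_sites(m.sequence, arms):
        site = AttSite.make(hit["site_type"], hit["overlap"], hit["orientation"], arms)
        feats.append(Feature(
            kind="att_site", start=hit["start"], end=hit["end"],
            strand="+" if hit["orientation"] == "forward" else "-",
            label=site.label(), att=site))
    feats.sort(key=lambda f: f.start)
    return DnaMolecule(m.id, m.sequence, m.topology, feats)


# -- I/O -------------------------------------------------------------------

def _to_record(m: DnaMolecule) -> SeqRecord:
    rec = SeqRecord(Seq(m.sequence), id=m.id, name=m.id[:16] or "mol", description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = m.topology
    L = len(m.sequence)
    for f in m.features:
        strand = 1 if f.strand == "+" else -1
        if f.wraps:
            loc = CompoundLocation([FeatureLocation(f.start, L, strand),
                                    FeatureLocation(0, f.end, strand)])
        else:
            loc = FeatureLocation(f.start, f.end, strand)
        quals = {"label": [f.label], "sira_kind": [f.kind]}
        if f.att is not None:
            quals.update({
                "site_type": [f.att.site_type],
                "overlap": [f.att.overlap],
                "channel": [f.att.channel.name],
                "orientation": [f.att.orientation],
                "left_arm": [f.att.left_arm],
                "right_arm": [f.att.right_arm],
            })
        rec.features.append(SeqFeature(loc, type=_KIND_TO_KEY[f.kind], qualifiers=quals))
    return rec


def _from_record(rec: SeqRecord) -> DnaMolecule:
    topology = rec.annotations.get("topology", "linear")
    seq = str(rec.seq).upper()
    feats = []
    for sf in rec.features:
        kind = sf.qualifiers.get("sira_kind", [_KEY_TO_KIND.get(sf.type, "")])[0]
        if kind not in FEATURE_KINDS:
            continue  # foreign annotation; not part of the model
        if isinstance(sf.location, CompoundLocation):
            parts = sorted(sf.location.parts, key=lambda p: int(p.start))
            start, end = int(parts[-1].start), int(parts[0].end)
        else:
            start, end = int(sf.location.start), int(sf.location.end)
        strand = "-" if sf.location.strand == -1 else "+"
        label = sf.qualifiers.get("label", [""])[0]
        att = None
        if kind == "att_site":
            try:
                site_type = sf.qualifiers["site_type"][0]
                overlap = sf.qualifiers["overlap"][0]
            except KeyError as exc:
                raise ValidationError(
                    f"record {rec.id}: att_site feature missing qualifier {exc}") from exc
            orientation = sf.qualifiers.get(
                "orientation", ["forward" if strand == "+" else "reverse"])[0]
            if channel_of(overlap).name != sf.qualifiers.get(
                    "channel", [channel_of(overlap).name])[0]:
                raise ValidationError(
                    f"record {rec.id}: channel qualifier disagrees with overlap {overlap}")
            if "left_arm" in sf.qualifiers and "right_arm" in sf.qualifiers:
                att = AttSite(site_type, overlap,
                              sf.qualifiers["left_arm"][0], sf.qualifiers["right_arm"][0],
                              orientation)
            else:
                att = AttSite.make(site_type, overlap, orientation)
        feats.append(Feature(kind, start, end, strand, label, att))
    return DnaMolecule(rec.id, seq, topology, feats)


def read_genbank(path) -> list[DnaMolecule]:
    """Read all records of a GenBank file (LOCUS topology honored)."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValidationError(f"malformed GenBank in {path}: {exc}") from exc
    if not records and path.read_text().strip():
        raise ValidationError(f"malformed GenBank in {path}: no parseable records")
    return [_from_record(r) for r in records]


def write_genbank(molecules, path) -> None:
    """Write molecules to one GenBank file."""
    records = [_to_record(m) for m in molecules]
    SeqIO.write(records, str(Path(path)), "genbank")


def read_fasta(path, iupac_ok: bool = False) -> list[DnaMolecule]:
    """Read FASTA as linear, featureless molecules (sequences uppercased).

    Non-ACGT letters are rejected unless ``iupac_ok`` (designer inputs such
    as degenerate RBS strings are handled upstream and never reach here).
    """
    mols = []
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        extra = set(seq) - set("ACGT")
        if extra and not iupac_ok:
            raise ValidationError(f"record {rec.id}: non-ACGT letters {sorted(extra)}")
        mols.append(DnaMolecule(rec.id, seq, "linear", []))
    return mols


def molecule_summary(m: DnaMolecule) -> dict:
    """JSON-serializable summary used by CLI reports."""
    return {
        "id": m.id,
        "length": len(m.sequence),
        "topology": m.topology,
        "features": [
            {"kind": f.kind, "label": f.label, "start": f.start, "end": f.end,
             "strand": f.strand,
             **({"site": f.att.label(), "channel": f.att.channel.name}
                if f.att is not None else {})}
            for f in sorted(m.features, key=lambda f: f.start)
        ],
    }
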