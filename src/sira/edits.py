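"""Post-assembly editing: replacing or adding genes inside an array.

A finished assembly is an array of payload cassettes separated by attL
sites, each on its own channel. With integrase + RDF, each attL recombines
with a matching attR, so any junction-bounded segment can be swapped out.
Direct one-step replacement is possible but inefficient in practice, so the
default plan is two-step:

1. Replace the target segment with a counter-selectable ccdB-CmR cassette
   flanked by attR sites matching the two junction channels of the target
   (integrase + RDF). Because adjacent junctions alternate placement
   orientation, both plasmid-side junction products come out as attB sites
   flanking the cassette.
2. Replace the cassette with 1-5 new cassettes in an ordinary attP x attB
   reaction (integrase alone). The remaining attL sites in the array are
   inert under these conditions.

Adding genes is the same plan with the original gene included among the
new parts; replacing one gene of a five-gene array with three parts yields
the published seven-gene arithmetic (n - 1 + m payloads in general).
"""

from __future__ import annotations

from dataclasses import dataclass

from .att import DESIGN_OVERLAP_ORDER, ArmSet, AttSite, DEFAULT_ARMS, channel_of
from .design import (
    AssemblyScheme, Part, build_cassette, junction_product_site, plan_assembly,
    predict_assembly,
)
from .errors import CapacityError, DesignError
from .molecules import DnaMolecule, Feature

# Placeholder counter-selectable cassette body: a ccdB stand-in followed by a
# chloramphenicol-resistance stand-in. Synthetic sequences, fixed so plans
# are deterministic; real users substitute the genuine cassette.
_CCDB_STUB = ("ATGCAGTTTAAGGTTTACACCTATAAAAGAGAGAGCCGTTATCGTCTGTTTGTGGATGTA"
              "CAGAGTGATATTATTGACACGCCCGGGCGACGGATGGTGATCC")
_CMR_STUB = ("ATGGAGAAAAAAATCACTGGATATACCACCGTTGATATATCCCAATGGCATCGTAAAGAA"
             "CATTTTGAGGCATTTCAGTCAGTTGCTCAATGTACCTATAACC")


def default_cassette_body() -> tuple[str, list[tuple[str, str, int, int]]]:
    """Sequence and (kind, label, start, end) features of the packaged
    ccdB-CmR placeholder body."""
    seq = _CCDB_STUB + _CMR_STUB
    feats = [("marker", "ccdB", 0, len(_CCDB_STUB)),
             ("marker", "CmR", len(_CCDB_STUB), len(seq))]
    return seq, feats


@dataclass(frozen=True)
class EditPlan:
    """A two-step edit: cassette exchange in, new parts in.

    ``step1_cassette`` is the attR-flanked counter-selectable cassette
    (None when the assembly already carries it); ``intermediate`` is the
    predicted product of step 1 (attL x attR, integrase + RDF);
    ``step2_cassettes`` are the att-tailed amplicons of the new parts;
    ``final`` is the predicted product of step 2 (attP x attB, integrase
    alone). ``caveats`` records design compromises such as channel reuse.
    """

    target_label: str
    new_parts: tuple[Part, ...]
    step1_cassette: DnaMolecule | None
    intermediate: DnaMolecule
    step2_scheme: AssemblyScheme
    step2_cassettes: tuple[DnaMolecule, ...]
    final: DnaMolecule
    caveats: tuple[str, ...] = ()


def _target_flanks(assembly: DnaMolecule, target_label: str):
    """The target payload feature and its two flanking attL features."""
    pays = [ (i, f) for i, f in enumerate(assembly.features)
             if f.kind in ("payload", "marker") and f.label == target_label]
    if not pays:
        raise DesignError(f"no payload {target_label!r} in {assembly.id}")
    ti, target = pays[0]
    atts = [(i, f) for i, f in enumerate(assembly.features) if f.kind == "att_site"]
    if len(atts) < 2:
        raise DesignError(f"{assembly.id}: fewer than two att sites")
    L = len(assembly)

    def gap_forward(frm: int, to: int) -> int:  # distance walking 5'->3'
        return (to - frm) % L

    t_start = target.start
    t_end = target.end if not target.wraps else target.end + L
    left = min(atts, key=lambda kv: gap_forward(kv[1].end % L, t_start))
    right = min(atts, key=lambda kv: gap_forward(t_end % L, kv[1].start))
    if left[0] == right[0]:
        raise DesignError(f"target {target_label!r} is not junction-bounded")
    la, ra = left[1].att, right[1].att
    if la.site_type != "L" or ra.site_type != "L":
        raise DesignError(
            f"target {target_label!r} flanks are {la.label()}/{ra.label()}, "
            "not attL sites (segment is not editable by attL x attR)")
    if la.channel == ra.channel or la.channel.symmetric or ra.channel.symmetric:
        raise DesignError("target flanks must use two distinct asymmetric channels")
    return (ti, target), left, right


def _build_r_cassette(left_att: AttSite, right_att: AttSite, body_seq: str,
                      body_feats, mol_id: str, arms: ArmSet) -> DnaMolecule:
    """attR-flanked cassette matching the target's two flanks as placed."""
    rl = AttSite.make("R", left_att.overlap, left_att.orientation, arms)
    rr = AttSite.make("R", right_att.overlap, right_att.orientation, arms)
    lseq, rseq = rl.placed_sequence, rr.placed_sequence
    seq = lseq + body_seq + rseq
    feats = [Feature("att_site", 0, len(lseq),
                     "+" if rl.orientation == "forward" else "-", rl.label(), rl)]
    for kind, label, s, e in body_feats:
        feats.append(Feature(kind, s + len(lseq), e + len(lseq), "+", label))
    feats.append(Feature("att_site", len(lseq) + len(body_seq), len(seq),
                         "+" if rr.orientation == "forward" else "-", rr.label(), rr))
    return DnaMolecule(mol_id, seq, "linear", feats)


def _replace_segment(assembly: DnaMolecule, left_idx: int, right_idx: int,
                     up_new: AttSite, down_new: AttSite,
                     body_seq: str, body_feats, new_id: str) -> DnaMolecule:
    """Predicted plasmid product: everything from the left flank through the
    right flank is replaced by junction + body + junction."""
    lf = assembly.features[left_idx]
    framed = assembly.rotated(lf.start)
    rf = framed.features[right_idx]
    if rf.wraps:
        raise DesignError("flanking sites overlap the target segment")
    lf = framed.features[left_idx]
    jl_site, jl_strand = junction_product_site(lf.att, up_new)
    jr_site, jr_strand = junction_product_site(down_new, rf.att)
    jl_seq, jr_seq = jl_site.placed_sequence, jr_site.placed_sequence
    seq = jl_seq + body_seq + jr_seq + framed.sequence[rf.end:]
    feats = [Feature("att_site", 0, len(jl_seq), jl_strand, jl_site.label(), jl_site)]
    pos = len(jl_seq)
    for kind, label, s, e in body_feats:
        feats.append(Feature(kind, s + pos, e + pos, "+", label))
    pos += len(body_seq)
    feats.append(Feature("att_site", pos, pos + len(jr_seq), jr_strand,
                         jr_site.label(), jr_site))
    pos += len(jr_seq)
    for i, f in enumerate(framed.features):
        if f.wraps or f.start < rf.end:
            continue
        feats.append(Feature(f.kind, f.start - rf.end + pos, f.end - rf.end + pos,
                             f.strand, f.label, f.att))
    return DnaMolecule(new_id, seq, assembly.topology,
                       sorted(feats, key=lambda f: f.start))


def _pick_step2_channels(intermediate: DnaMolecule, n_parts: int,
                         cL: str, cR: str) -> tuple[list[str], list[str]]:
    """Interior junction channels for step 2: prefer channels absent from
    the array; fall back to channels present only as inert attL sites."""
    needed = n_parts - 1
    flank_chans = {channel_of(cL), channel_of(cR)}
    used = {f.att.channel for f in intermediate.att_features()}
    fresh = [c for c in DESIGN_OVERLAP_ORDER
             if channel_of(c) not in used and channel_of(c) not in flank_chans]
    reusable = [c for c in DESIGN_OVERLAP_ORDER
                if channel_of(c) in used and channel_of(c) not in flank_chans]
    caveats = []
    chosen = fresh[:needed]
    if len(chosen) < needed:
        borrow = reusable[: needed - len(chosen)]
        chosen += borrow
        caveats.append(
            "channel reuse: interior junctions " + ",".join(borrow) + " duplicate "
            "channels already present as attL sites; the reaction is orthogonal "
            "under integrase alone, but later attL x attR edits at these "
            "channels will be ambiguous")
    if len(chosen) < needed:
        raise CapacityError(
            f"{n_parts} new parts need {needed} interior channels; only "
            f"{len(chosen)} available")
    return chosen, caveats


def plan_replacement(assembly: DnaMolecule, target_label: str, new_parts,
                     arms: ArmSet = DEFAULT_ARMS) -> EditPlan:
    """Two-step plan replacing one junction-bounded payload with 1-5 parts."""
    new_parts = tuple(new_parts)
    if not 1 <= len(new_parts) <= 5:
        raise CapacityError(f"can insert 1-5 parts per edit, got {len(new_parts)}")
    (_, _target), (li, lf), (ri, rf) = _target_flanks(assembly, target_label)
    body_seq, body_feats = default_cassette_body()
    cassette = _build_r_cassette(lf.att, rf.att, body_seq, body_feats,
                                 f"ccdB-CmR_{target_label}", arms)
    cas_left = cassette.features[0].att
    cas_right = cassette.att_features()[-1].att
    intermediate = _replace_segment(
        assembly, li, ri, cas_left, cas_right, body_seq, body_feats,
        f"{assembly.id}.{target_label}-to-ccdB")
    interior, caveats = _pick_step2_channels(
        intermediate, len(new_parts), lf.att.overlap, rf.att.overlap)
    site_set = [lf.att.overlap] + interior + [rf.att.overlap]
    scheme2 = plan_assembly(new_parts, intermediate, site_set=site_set, arms=arms)
    step2_cassettes = tuple(
        build_cassette(p, spec) for p, spec in zip(new_parts, scheme2.position_sites))
    final = predict_assembly(scheme2, new_parts, intermediate)
    return EditPlan(
        target_label=target_label,
        new_parts=new_parts,
        step1_cassette=cassette,
        intermediate=intermediate,
        step2_scheme=scheme2,
        step2_cassettes=step2_cassettes,
        final=final,
        caveats=tuple(caveats),
    )


def plan_addition(assembly: DnaMolecule, junction_segment: str, new_parts,
                  arms: ArmSet = DEFAULT_ARMS) -> EditPlan:
    """Add parts at a junction-bounded segment.

    ``junction_segment`` names the segment to open up. If it is the already
    inserted counter-selectable cassette (a ccdB-labelled body flanked by
    attB/attP pairs), only step 2 is planned; otherwise this is
    :func:`plan_replacement` with the segment's original payload expected
    among ``new_parts`` (add k genes to an n-gene array by replacing one
    gene with itself plus k extras: n - 1 + m payloads result).
    """
    new_parts = tuple(new_parts)
    if not 1 <= len(new_parts) <= 5:
        raise CapacityError(f"can insert 1-5 parts per edit, got {len(new_parts)}")
    seg = [f for f in assembly.features
           if f.kind in ("payload", "marker") and f.label == junction_segment]
    if seg and "ccdb" in junction_segment.lower():
        # assembly already carries the exchangeable cassette: step 1 is done
        sites = assembly.att_features()
        vec_like = [f for f in sites if f.att.site_type in "PB"]
        if len(vec_like) != 2:
            raise DesignError(
                f"{assembly.id}: expected exactly 2 attB/attP sites flanking "
                f"{junction_segment!r}, found {len(vec_like)}")
        cL, cR = (f.att.overlap for f in vec_like)
        interior, caveats = _pick_step2_channels(assembly, len(new_parts), cL, cR)
        site_set = [cL] + interior + [cR]
        scheme2 = plan_assembly(new_parts, assembly, site_set=site_set, arms=arms)
        step2_cassettes = tuple(
            build_cassette(p, spec)
            for p, spec in zip(new_parts, scheme2.position_sites))
        final = predict_assembly(scheme2, new_parts, assembly)
        return EditPlan(junction_segment, new_parts, None, assembly, scheme2,
                        step2_cassettes, final, tuple(caveats))
    return plan_replacement(assembly, junction_segment, new_parts, arms)
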