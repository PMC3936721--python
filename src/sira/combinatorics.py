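"""Combinatorial library enumeration.

Because every att site recombines only within its channel, mixing several
candidate cassettes per position in one reaction yields the Cartesian
product of the candidates: with three genes offered at each of three
positions, 27 assemblies are possible, of which the 3! = 6 permutations
carry one copy of each gene (expected correct fraction 6/27 = 22%).
Degenerate RBS primers multiply instead over sequence space: a 16-fold
degenerate RBS per gene across five genes encodes 16^5 = 1,048,576 operons.

Counts are always computed arithmetically (exact products of per-position
multiplicities); materialization is capped, so astronomically large
libraries still report exact totals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace as dc_replace
from fractions import Fraction
from math import prod

from Bio.Data.IUPACData import ambiguous_dna_values

from .design import AssemblyScheme, Part, predict_assembly
from .errors import ValidationError
from .molecules import DnaMolecule


@dataclass(frozen=True)
class PositionalPartSet:
    """Candidate parts per assembly position (1..n). All candidates at one
    position carry that position's site specs, so any choice recombines the
    same way."""

    positions: tuple[tuple[Part, ...], ...]

    def __post_init__(self):
        if not self.positions:
            raise ValidationError("positional part set has no positions")
        for i, cands in enumerate(self.positions):
            if not cands:
                raise ValidationError(f"position {i + 1} has no candidates")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(p.id for cands in self.positions for p in cands)


@dataclass(frozen=True)
class LibraryMember:
    labels: tuple[str, ...]
    correct: bool
    product: DnaMolecule | None = None
    annotation: str = ""


@dataclass(frozen=True)
class LibraryReport:
    """Enumeration summary. ``total_combinations`` is always exact;
    ``members`` may be truncated (``truncated`` flag), in which case the
    correct count/fraction refer to the enumerated prefix."""

    total_combinations: int
    members: tuple[LibraryMember, ...]
    correct_count: int
    correct_fraction: Fraction
    truncated: bool = False

    @property
    def correct_percentage(self) -> float:
        return 100.0 * float(self.correct_fraction)


def one_of_each(universe):
    """Default composition predicate: every distinct payload exactly once."""
    want = frozenset(universe)

    def pred(labels: tuple[str, ...]) -> bool:
        return len(labels) == len(want) and frozenset(labels) == want

    return pred


def enumerate_library(pset: PositionalPartSet, vector: DnaMolecule,
                      scheme: AssemblyScheme | None = None,
                      predicate=None, max_members: int = 10_000,
                      build_products: bool = True) -> LibraryReport:
    """Cartesian-product enumeration of a randomized-position library.

    Every member's product is built by :func:`~sira.design.predict_assembly`
    (engine-free string construction). The composition predicate defaults to
    "one copy of each distinct payload"; the report carries the exact
    rational correct fraction.
    """
    from .design import plan_assembly
    total = prod(len(c) for c in pset.positions)
    if scheme is None:
        # site assignments depend only on the position, not the candidate
        placeholders = [dc_replace(c[0], id=f"pos{i + 1}")
                        for i, c in enumerate(pset.positions)]
        scheme = plan_assembly(placeholders, vector)
    predicate = predicate or one_of_each(pset.universe)
    members = []
    correct = 0
    truncated = False
    for combo in itertools.product(*pset.positions):
        if len(members) >= max_members:
            truncated = True
            break
        labels = tuple(p.id for p in combo)
        ok = bool(predicate(labels))
        product = None
        if build_products:
            member_scheme = dc_replace(scheme, part_ids=labels)
            product = predict_assembly(member_scheme, combo, vector)
        if ok:
            correct += 1
        members.append(LibraryMember(labels, ok, product))
    denom = len(members) if truncated else total
    return LibraryReport(
        total_combinations=total,
        members=tuple(members),
        correct_count=correct,
        correct_fraction=Fraction(correct, denom) if denom else Fraction(0),
        truncated=truncated,
    )


def expand_degenerate(iupac: str, limit: int | None = None) -> dict:
    """Expand an IUPAC-degenerate DNA string.

    Returns ``{"count": exact number of encoded sequences, "sequences":
    lexicographic enumeration, truncated at limit}``.
    """
    if not isinstance(iupac, str) or not iupac:
        raise ValidationError("degenerate string must be a non-empty string")
    s = iupac.upper().replace("U", "T")
    choices = []
    for ch in s:
        if ch not in "ACGTRYSWKMBDHVN":
            raise ValidationError(f"invalid IUPAC code {ch!r} in {iupac!r}")
        choices.append("".join(sorted(ambiguous_dna_values[ch])))
    count = prod(len(c) for c in choices)
    sequences = []
    for combo in itertools.product(*choices):
        if limit is not None and len(sequences) >= limit:
            break
        sequences.append("".join(combo))
    return {"count": count, "sequences": sequences}


def rbs_library(parts, degenerate_rbs_map: dict, scheme: AssemblyScheme,
                max_members: int = 10_000) -> LibraryReport:
    """Library over degenerate-RBS expansions at a fixed gene order.

    ``degenerate_rbs_map`` maps part id -> IUPAC string (parts without an
    entry keep their designed RBS). Each member records the concrete RBS
    chosen per gene; the total is the exact product of per-gene counts.
    """
    parts = list(parts)
    if tuple(p.id for p in parts) != scheme.part_ids:
        raise ValidationError("parts do not match the scheme's part order")
    unknown = set(degenerate_rbs_map) - {p.id for p in parts}
    if unknown:
        raise ValidationError(f"degenerate RBS for unknown parts: {sorted(unknown)}")
    per_gene = []
    for p in parts:
        if p.id in degenerate_rbs_map:
            per_gene.append(expand_degenerate(degenerate_rbs_map[p.id])["sequences"])
        else:
            per_gene.append([p.rbs])
    total = prod(len(v) for v in per_gene)
    members = []
    truncated = False
    for combo in itertools.product(*per_gene):
        if len(members) >= max_members:
            truncated = True
            break
        labels = tuple(f"{p.id}:{rbs}" for p, rbs in zip(parts, combo))
        members.append(LibraryMember(labels, True))
    return LibraryReport(
        total_combinations=total,
        members=tuple(members),
        correct_count=len(members) if truncated else total,
        correct_fraction=Fraction(1),
        truncated=truncated,
    )
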