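"""Tuning expression with degenerate RBS primers.

An IUPAC-degenerate RBS in the forward primer encodes a small library of
translation-initiation strengths per gene. A 16-fold design at each of five
genes gives 16^5 = 1,048,576 operon variants; counts are exact even though
only a capped sample is materialized.
"""

from sira.combinatorics import expand_degenerate, rbs_library
from sira.fixtures import FixtureSpec, generate_fixtures

deg = "RYAGGAGGNA"  # R,Y: 2-fold each; N: 4-fold -> 16 sequences
out = expand_degenerate(deg)
print(f"{deg} expands to {out['count']} sequences, e.g. "
      f"{', '.join(out['sequences'][:4])}, ...")

fx = generate_fixtures(FixtureSpec(
    seed=1, n_parts=5, part_labels=("vioA", "vioB", "vioC", "vioD", "vioE")))
report = rbs_library(fx.parts, {p.id: deg for p in fx.parts}, fx.scheme,
                     max_members=5)
print(f"\nfive genes x 16 RBS variants = {report.total_combinations:,} "
      f"operon designs (enumeration capped at {len(report.members)})")
print("first sampled member (gene:RBS choices):")
for lbl in report.members[0].labels:
    print("  ", lbl)
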