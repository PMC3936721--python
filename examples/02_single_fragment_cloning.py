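"""Single-fragment cloning by cassette exchange.

A KanR cassette amplified with attP^TT / attP^TC tails replaces the ccdB
segment of a vector carrying matching attB sites. Two crossovers do it:
integration into a linear co-integrate, then intramolecular resolution.
"""

from sira import INT_ONLY, ReactionState, classify_products, react_to_closure
from sira.design import build_cassette
from sira.fixtures import FixtureSpec, generate_fixtures

fx = generate_fixtures(FixtureSpec(seed=1, n_parts=1, part_labels=("KanR",)))
cassette = build_cassette(fx.parts[0], fx.scheme.position_sites[0])
print("vector:", len(fx.vector), "bp circular;",
      [f.att.label() for f in fx.vector.att_features()])
print("cassette:", len(cassette), "bp linear;",
      [f.att.label() for f in cassette.att_features()])

(terminal,) = react_to_closure(ReactionState.make([fx.vector, cassette], INT_ONLY))
print("\nterminal molecules:")
for m in terminal.molecules:
    labels = [f.label for f in m.features if f.kind in ("payload", "marker")]
    print(f"  {m.topology:8s} {len(m):5d} bp  carrying {labels}")

report = classify_products([terminal], fx.scheme)
product = report["correct"][0]
print("\nexchanged plasmid payloads:", product.payload_labels(),
      "| junctions:", [f.att.label() for f in product.att_features()])
print("ccdB left on the excised linear fragment; the plasmid is selectable "
      "by ccdB loss.")
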