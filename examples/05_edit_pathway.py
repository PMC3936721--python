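"""Editing an assembled pathway: replace one gene, then add three more.

The array's attL junctions are addressable with integrase + RDF. The
two-step plan first swaps the target for a ccdB-CmR cassette (attL x attR),
leaving it flanked by attB sites, then replaces the cassette with new
att-tailed parts under integrase alone, where the remaining attL sites are
inert.
"""

from sira import INT_ONLY, INT_RDF, Part, ReactionState, react_to_closure
from sira.edits import plan_addition, plan_replacement
from sira.fixtures import FixtureSpec, generate_fixtures
from sira.molecules import identity_key

fx = generate_fixtures(FixtureSpec(
    seed=1, n_parts=5, part_labels=("crtB", "crtE", "crtI", "crtZ", "crtY")))
asm = fx.prebuilt_assembly
print("starting array:", asm.payload_labels())


def engine_confirms(mols, cond, predicted):
    keys = {identity_key(m) for s in
            react_to_closure(ReactionState.make(mols, cond))
            for m in s.molecules}
    return identity_key(predicted) in keys


new_crtI = Part("crtI", "ATG" + "ACGTGGCATC" * 8, "TAAGGAGGCA")
plan = plan_replacement(asm, "crtI", [new_crtI])
print("\nreplace crtI: step-1 cassette sites:",
      [f.att.label() for f in plan.step1_cassette.att_features()])
print("intermediate exchange sites:",
      [f.att.label() for f in plan.intermediate.att_features()
       if f.att.site_type in "PB"], "(two attB, as selected for)")
print("step 1 engine-verified:",
      engine_confirms([asm, plan.step1_cassette], INT_RDF, plan.intermediate))
print("step 2 engine-verified:",
      engine_confirms([plan.intermediate, *plan.step2_cassettes], INT_ONLY,
                      plan.final))

extras = [Part(x, "ATG" + "GGCATCACGT" * 7, "TAAGGAGGCA")
          for x in ("idi", "dxs", "ispA")]
add = plan_addition(asm, "crtI", [new_crtI] + extras)
print("\nadd 4 parts at the crtI locus ->",
      len(add.final.payload_labels()), "payloads:",
      add.final.payload_labels())
for c in add.caveats:
    print("caveat:", c)
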