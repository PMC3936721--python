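# Methods

## The recombination model

An att site is modeled as `left_arm | overlap | right_arm` in its own
forward frame, with a type (P, B, L, R), a 2 nt overlap, and a placement
orientation on its host molecule. Arm composition is fixed by type via the
standard serine-integrase convention attL = B-arm|overlap|P-arm and
attR = P-arm|overlap|B-arm; this lives in one constant
(`sira.att.HALF_SITE_ORIGIN`) so the convention could be flipped in a
single place. The packaged default arms are arbitrary, pairwise-distinct
22-mers (46 bp total site, the ϕC31 scale); users supply the natural arm
sequences through `ArmSet`. All logic is arm-agnostic.

**Compatibility.** Two sites can recombine iff (i) the type pair is {P,B}
with integrase alone or {L,R} with integrase + RDF, and (ii) their
*effective* overlaps match, where the effective overlap of a
reverse-placed site is the reverse complement of its stored overlap. Sites
on a symmetric (self-complementary) channel match in both relative
orientations. Overlap identity is binary: the experimental literature
reports that the overlap sequence has little effect on efficiency, and no
per-channel rates exist, so all channels are treated as equal and no
kinetics are modeled.

**Free molecules have no strand.** Canonical molecule identity
(`normalize`) picks the lexicographically least rotation over both strands
of a circle (Booth's algorithm) or the lesser strand of a linear; the
engine may therefore see either strand of an input. For *intermolecular*
pairs an event exists whenever the channels match: if the placed polarities
oppose, the event records `flip_b` and proceeds with molecule b flipped.
Without this rule the simulated outcome would depend on the arbitrary
normalization frame. *Intramolecular* placement is physically meaningful
and uses the strict effective-overlap rule: matched sites in direct repeat
excise (circle → two circles, linear → linear + circle), in inverted repeat
they invert the intervening segment.

**Crossover surgery.** Both participating sites are framed forward, each
molecule is cut just 3′ of the overlap, and the halves are cross-joined;
junction features are re-derived as hybrid sites rather than copied
(attP × attB → attL/attR; attL × attR → attP/attB). Same-orientation pairs
yield the canonical hybrids. Antiparallel pairs (same channel, opposed
polarity, e.g. forward attP^TT × reversed attB^AA) join like half-sites, so
their hybrids carry a reverse-complemented arm on the distal side; they are
typed L/R by half-site origin, which keeps directionality gating correct.
Features overlapping a cut other than the consumed sites are dropped
(designs never place payloads over att sites). For mismatched events
(`allow_mismatch`) the junction records the upstream site's overlap; no
molecular detail of mismatched strand exchange is modeled, and no rate is
attached.

**Conservation accounting.** Every crossover conserves the duplex (both-
strand) base count exactly (`duplex_base_count`). Top-strand counts
(`total_base_count`) are additionally conserved by polarity-aligned events,
but an event that reads one molecule on its bottom strand swaps A/T and
C/G in top-strand bookkeeping; the property suite asserts both statements
at their proper strength.

**Closure.** `react_to_closure` runs breadth-first over reaction states
(multisets of normalized molecules plus the enzyme condition), branching
over every enumerated event — alternative event choices are explored as
branches rather than simulating concentrations, which reproduces the
qualitative product spectrum without kinetics. States deduplicate by
normalized identity; termination follows because each event consumes the
condition's reactive type pair. Default limits (max_events 50,
max_molecules 200, max_states 10 000) stop runaways explicitly — hitting a
limit raises an error carrying partial results, never a silent truncation.
Desk-scale designs close far below these limits.

## Assembly planning conventions

* **Channel order.** Junctions run TT, CT, GT, CA, CC, TC left to right
  (the published 3-fragment assignments extend this way), with the first
  and last equal to the vector's two channels. A vector contributes two
  junctions, so n fragments need n+1 distinct asymmetric channels: capacity
  is 5 with one integrase's six channels.
* **Type alternation.** Cassettes alternate attP-type and attB-type
  starting with the opposite of the vector's site type; the final
  cassette's distal site always opposes the vector's second site. For even
  n this makes exactly one mixed P/B cassette — the published signature of
  the four-gene scheme.
* **Junction orientations alternate.** Cassettes carry their two sites in
  inverted repeat (reducing forward/reverse primer complementarity), which
  forces the effective overlap at successive junctions to alternate between
  the channel dinucleotide and its reverse complement. The packaged vector
  therefore has its second attB reversed. For even n the parity cannot
  close on a fixed vector, so the mixed final cassette carries parallel
  sites instead. A side effect worth knowing: this orientation alternation
  is exactly what makes the two-step edit (below) leave the
  counter-selectable cassette flanked by two attB sites. The published
  figures do not state site orientations; this is the package's own
  documented convention, and the planner validates any explicit
  `site_set` override against the same compatibility rules.
* **Primers.** The forward primer is placed-left-site + RBS + the payload's
  first 20 nt (annealing region); the reverse primer is the placed right
  site reverse-complemented + the payload's last 20 nt reverse-
  complemented. Annealing length is a parameter; melting-temperature
  optimization is out of scope. `amplicon_of` re-derives the amplicon from
  primers at string level, and site detection on the amplicon must return
  the scheme's specs — this closes the loop between primer emission and
  the recombination model.
* **Prediction vs simulation.** `predict_assembly` builds the product by
  direct string construction (junction sites from the same half-site
  algebra the engine uses, payloads in order, vector backbone closing the
  circle) and must equal the unique correct closure product under
  normalized identity; the test suite enforces this for n = 1..5 and for
  every library member and edit plan it checks.

## Editing

The default edit is two-step, mirroring the observation that direct
attL × attR replacement is less efficient than attP × attB assembly:
step 1 exchanges the target segment for a ccdB-CmR cassette flanked by
attR sites matching the target's two junction channels (integrase + RDF);
step 2 replaces the cassette with 1–5 new att-tailed parts (integrase
alone), the remaining attL sites being inert under that condition. The
cassette body is an opaque placeholder with ccdB/CmR marker annotations —
counter-selection biology is reflected only in product classification,
never simulated. Interior channels for step 2 prefer channels absent from
the array; when a five-gene array (which consumes all six channels) is
edited with multiple parts, channels held by inert attL sites are reused
and the plan records a caveat, because reuse is sound for the reaction
itself but makes *future* attL × attR edits at those channels ambiguous.
Payload arithmetic is n − 1 + m for every edit.

## What the fixtures emulate — and what they do not

`generate_fixtures` builds a circular vector (attB^TT forward, removable
ccdB placeholder, attB^TC reversed, AmpR-tagged backbone) and parts with
random payloads (default 60–120 nt; tests use 40–70 nt to keep closure
states small) whose sequences are guaranteed free of arm 22-mers, so
sequence-level site detection cannot produce spurious hits. Everything is
byte-deterministic in the seed. The fixtures emulate topology, site
layout and marker logic only: payloads are random DNA, not genes — no
codon structure, no promoters/terminators beyond annotations, no
biological efficiencies. Passing tests therefore certify the combinatorial
and recombinational logic, not wet-lab performance; experimentally
observed transformation efficiencies and percent-correct rates are
biological outcomes outside the model.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; GenBank 1-based closed
  conversion happens only at the file boundary. Circular features may wrap
  the origin (`end <= start`).
* Normalization ties (rotationally periodic sequences, strand-palindromes)
  resolve by the least feature tuple, making identity fully deterministic.
* Library counts are always computed arithmetically; materialization is
  capped (default 10 000 members) with an explicit `truncated` flag, so
  16⁵-scale RBS libraries report exact totals without being built.
* Degenerate RBS strings accept the 15 IUPAC nucleotide codes; expansion
  is lexicographic and truncatable with the count still exact.
* `classify_products` sorts terminal circles into correct (ccdB-free,
  all scheme payloads exactly once in cyclic scheme order, co-oriented),
  misassembled (ccdB-free otherwise) and vector_reformed (ccdB present) —
  the in-silico analogue of ccdB counter-selection plus a structure check.

## Known limitations

No kinetics, no synapsis/cleavage intermediates, no supercoiling: the
reported abortive cleavage at mismatched attL sites under integrase + RDF
is represented only as the planner's caveat strings. Mismatched
intermolecular and intramolecular events are treated identically under
`allow_mismatch`, with no frequency attached. Only one integrase's site
set ships; the type system permits others but no second arm set is
packaged. SBOL serialization and sequence alignment are out of scope.
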