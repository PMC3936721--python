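# sira

Design and in-silico simulation of **serine-integrase recombinational
assembly (SIRA)**: ϕC31-type attP/attB cassette exchange, ordered
multi-fragment pathway assembly, post-assembly gene replacement/addition,
and combinatorial library enumeration.

## The problem and who this is for

ϕC31 integrase recombines a ~46 bp *attP* site with a ~46 bp *attB* site by
cutting both with a two-nucleotide stagger around a central 2 bp "overlap",
exchanging the half-sites, and rejoining them as the hybrid sites *attL* and
*attR*. Two rules make this a cloning technology:

* **Orthogonality.** Sites recombine only when their overlaps match, and an
  overlap read on the other strand is its reverse complement, so the 16
  dinucleotides collapse into 6 asymmetric "channels" (TT/AA, CT/AG, GT/AC,
  CA/TG, CC/GG, TC/GA) plus 4 symmetric ones. Each asymmetric channel is an
  independent, orientation-enforcing junction.
* **Directionality.** With integrase alone only attP × attB reacts; adding
  the recombination directionality factor (RDF, gp3) switches specificity
  to attL × attR. Assemblies are therefore stable once made, yet every
  junction remains individually addressable for later edits.

With one vector (two junctions to the backbone) and six channels, up to
**five fragments** can be assembled in a defined order in a single pot; the
product is an array of cassettes separated by attL sites. Mixing several
candidates per position yields combinatorial libraries (3 genes × 3
positions → 27 combinations, 6 of them with one copy of each gene = 22%
expected correct), and degenerate-RBS primers multiply over sequence space
(16 variants per gene × 5 genes → 16⁵ = 1,048,576 operons).

The package is for synthetic biologists planning such experiments: it
assigns channels and site orientations, designs att-tailed primers,
predicts product maps, simulates the recombination reaction to closure
(including mismatch leakage and misassembly spectra), and plans two-step
edits — all on GenBank/FASTA inputs, with a deterministic toy-fixture
generator so everything runs without external data.

## Worked example

```python
from sira import INT_ONLY, ReactionState, classify_products, react_to_closure
from sira.design import build_cassette
from sira.fixtures import FixtureSpec, generate_fixtures

fx = generate_fixtures(FixtureSpec(seed=1, n_parts=3,
                                   part_labels=("crtB", "crtE", "crtI")))
print(fx.scheme.channel_order)
cassettes = [build_cassette(p, s)
             for p, s in zip(fx.parts, fx.scheme.position_sites)]
(terminal,) = react_to_closure(
    ReactionState.make([fx.vector] + cassettes, INT_ONLY))
report = classify_products([terminal], fx.scheme)
product = report["correct"][0]
print(len(product), product.payload_labels(),
      [f.att.label() for f in product.att_features()])
```

prints

```
('TT', 'CT', 'GT', 'TC')
820 ['crtE', 'crtI', 'crtB'] ['attL^GT', 'attL^CT', 'attL^TT', 'attL^TC']
```

i.e. the planner assigned the four junction channels TT→CT→GT→TC; the
reaction closed to a unique 820 bp circular plasmid carrying the three
genes in the designed (cyclic) order crtB–crtE–crtI, separated by four attL
junctions, one per channel. The listing order starts at the circle's
canonical origin — circular products have no natural start, so identity is
always judged after rotation/strand normalization.

The `examples/` directory has one short script per capability (channel
algebra, single-fragment cloning, pathway assembly, gene-order libraries,
pathway editing, degenerate RBS). A thin CLI covers the same ground from
the shell:

```bash
sira fixtures --seed 1 --n-parts 3 --out-dir fx
sira plan fx/parts.fasta fx/vector.gb --config fx/parts.yaml --out scheme.json
sira primers fx/parts.fasta fx/vector.gb --config fx/parts.yaml --amplicons amps.gb
sira simulate fx/vector.gb amps.gb --out report.json --products products.gb
```

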