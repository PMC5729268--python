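# retromark

Retroposon presence/absence markers as phylogenetic characters: simulation,
strict per-taxon calling, Dollo mapping with conflict detection, chimeric
SINE anatomy, and CpG-excluded divergence landscapes.

## The problem

Short interspersed elements (SINEs) and other retroposons insert into a
genome essentially once and are never precisely excised. An orthologous
locus where some species carry the element and others show the pristine
empty site is therefore a near-homoplasy-free binary character: the
present-state species should form a clade. Avian genomes are SINE-poor, but
passerine birds carry two young chimeric SINE families — each a
tRNA-derived head fused to the 3′ end of a CR1 LINE, ending in an 8-bp
`ATTCTRTG` microsatellite — whose insertions record the deepest branching
events of the passerine radiation.

`retromark` implements the full analysis as a reusable, tested pipeline:

- **`retromark.simulate`** — marker loci evolved along a rooted species
  tree under a Kimura 2-parameter (K2P) substitution process, with SINE
  insertions (head + tail + target-site duplication, TSD) planted on chosen
  branches, optional discordant placements emulating incomplete lineage
  sorting (ILS), and a per-locus truth table.
- **`retromark.markers`** — candidate locus discovery against an outgroup
  (empty-site signature) and per-taxon present/absent/ambiguous calls under
  the strict criteria: identical insertion point, orientation, element
  subtype and (when detectable) identical TSD, plus clear absence.
- **`retromark.phylo`** — presence/absence matrix, Dollo-consistent mapping
  onto the species tree, conflict flagging, and an exact binomial
  hard-polytomy test for branch support,
  `p = P(X ≥ n₁)` with `X ~ Binomial(n₁+n₂+n₃, 1/3)`.
- **`retromark.anatomy`** — majority-rule consensus, head/tail partitioning
  against tRNA and CR1 reference libraries, diagnostic tail sites, terminal
  microsatellite checks, diagnostic-copy screening.
- **`retromark.landscape`** — K2P distances
  `d = −½ ln[(1−2P−Q)·√(1−2Q)]` with pairwise deletion and exclusion of
  consensus CpG sites; binned family divergence landscapes.
- **`retromark.concat`** — element/TSD stripping and flank concatenation
  into a supermatrix (FASTA, relaxed PHYLIP, RAxML-style partitions) for
  external tree inference.

## Worked example

```python
import retromark as rm
from retromark import simulate as sim, trees

tree = trees.tree_from_newick(
    "(((((Taeniopygia,Corvus),(Menura,Climacteris)),(Pitta,Sayornis)),"
    "Acanthisitta),Gallus);")
for edge in tree.preorder_edge_iter():
    edge.length = 0.012

template = sim.make_sine_template(sim.SYNTH_TRNA_ILE, sim.SYNTH_CR1_TAIL,
                                  name="TguSINE1_synth")
cfg = sim.SimConfig(
    n_loci_per_branch={"Corvus,Taeniopygia": 6,
                       "Climacteris,Corvus,Menura,Taeniopygia": 6},
    seed=20, ils_probability=0.0)
loci, truths = sim.simulate_locus_set(tree, template, cfg)

library = sim.synthetic_library()
library[template.name] = template.sequence
records = [rm.validate_marker(l, rm.call_locus(l, library)) for l in loci]
print(f"valid markers: {sum(r.valid for r in records)}/{len(records)}")

matrix = rm.build_matrix(records)
mappings = rm.map_markers(matrix, tree)
print(f"conflicts: {sum(m.conflict for m in mappings)}")
from retromark.phylo import branch_support
for bid, s in branch_support(matrix, tree, mappings).items():
    if s.n_support:
        print(f"{bid}: {s.n_support}/{s.n_conflict_a}/{s.n_conflict_b} "
              f"p={s.p_value:.4f}")
```

prints

```
valid markers: 12/12
conflicts: 0
Climacteris,Corvus,Menura,Taeniopygia: 6/0/0 p=0.0014
Corvus,Taeniopygia: 6/0/0 p=0.0014
```

All twelve simulated insertions are recovered as valid markers with the
correct per-taxon states; none conflicts with the tree; each of the two
insertion branches is supported by six markers against zero for the
alternative quartet resolutions, giving the exact polytomy-test tail
probability (1/3)⁶ ≈ 0.0014.

The same pipeline is available from the shell:
`retromark simulate | call | map | anatomy | landscape | concat`
(see `retromark <cmd> --help`).

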