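# Methods

## The character model

A retroposon presence/absence marker is treated as a Dollo binary
character: the element is gained once, on one branch of a rooted species
tree, and never precisely excised. Under perfect data the present-state
taxa are exactly the leaves subtended by the insertion branch. Two
processes break this: incomplete lineage sorting (an insertion polymorphic
in the ancestral population sorts discordantly, so the present set matches
a *different* resolution of the local quartet than the species tree), and
calling error. The pipeline therefore separates (i) per-taxon state
calling with explicit ambiguity, (ii) marker-level validation, and (iii)
tree mapping that reports, but never resolves, conflicts.

## Synthetic data generator

`simulate_locus_set` emulates the data a presence/absence screen produces:

- **Flanks.** An ancestral flank of `2 × flank_length` nt (default 250 per
  side, the scale of typical presence/absence amplicons) evolves along
  every edge under a continuous-time Kimura 2-parameter model with
  transition/transversion rate ratio κ (`ts_tv_ratio`, default 2) and equal
  base frequencies. Per-site substitution probabilities come from the
  closed-form K2P transition matrix, so the generator and the K2P distance
  estimator are conjugate: realised divergence is an unbiased draw around
  the nominal branch length. No indel process is modelled — the true
  alignment is then trivially known, and alignment inference is explicitly
  out of scope.
- **Insertion.** On the designated branch the element (tRNA head + CR1
  tail, from `make_sine_template`) is inserted at the flank midpoint,
  duplicating the target site: the insertion-time target of length drawn
  uniformly from `tsd_length_range` (default 6–12 nt, inside the 4–20 nt
  range admissible for TSD detection) appears on both sides of the element.
  Each leaf's inserted copy — element plus both TSD copies — then decays
  *independently* by `copy_divergence` expected substitutions/site
  (default 0.06, the scale of a young SINE family averaging ~6 % to its
  consensus). Decaying the TSD copies with the element, rather than with
  the flank, makes the two copies exactly identical at zero decay and lets
  TSD detectability degrade realistically with copy age.
- **Column bookkeeping.** Absence rows show the original single target
  copy and gap columns across element + duplicated TSD, so all rows share
  one column frame and the per-locus "alignment" is exact by construction.
- **ILS.** With probability `ils_probability` (default 0.02, of the order
  of one marker in ~40) a marker's present set is drawn from the two
  discordant resolutions of the insertion branch's local quartet
  (children A, B; sibling clade C; discordant sets A∪C and B∪C). Branches
  without a local quartet (leaf branches, root children without a sibling)
  fall back to concordant placement. These discordant sets are never
  clades of a bifurcating tree, so every planted ILS marker is mappable as
  a conflict.
- **Orientation.** All insertions are forward-strand; `reverse_strand`
  flips every copy for negative tests of the orientation criterion.

What the generator does **not** emulate: indels and alignment error,
insertion-site preference, element truncation (5′-truncated copies),
precise excision, sequencing error, and lineage-specific rate variation.
Passing synthetic tests therefore demonstrates correctness of the calling
logic and mapping algebra under the stated model, not robustness to
misalignment — on real data, alignments should be inspected before calling,
as in any presence/absence study.

## Marker calling

Per-taxon classification automates by-eye validity criteria with stated
numeric surrogates (all configurable):

- *present*: element span ≤ 10 % gap; both junction columns within ±2 of
  the reference taxon's; best local-alignment library hit agrees with the
  reference in subtype and orientation; TSDs identical when detected in
  both rows ("if present": the criterion is skipped when either TSD is
  undetected, since post-insertion mutation routinely erases the exact
  repeat).
- *absent*: element span ≥ 90 % gap, and ≥ 50 % non-gap in a 10-column
  window on each side of the maximal gap run containing the span (the gap
  run is widened first because the duplicated-TSD columns are gaps in
  absence rows too).
- *ambiguous*: everything else, with reason codes.

TSD detection returns the longest exact direct repeat (4–20 nt) anchored
at both element junctions; anchoring at the junctions makes chance partial
matches rare, so a mutated TSD is usually reported as undetected rather
than as a spurious shorter repeat.

Reason codes split into two classes. Violations of a shared-insertion
criterion (shifted junction, subtype mismatch, orientation flip, TSD
mismatch) invalidate the whole marker: a copy at the right place with the
wrong anatomy is evidence of an independent insertion, not missing data.
Benign ambiguity (missing or partial sequence, discontiguous flanks)
produces a '?' cell and never invalidates — so validity is monotone under
adding taxa with no usable data.

Subtype assignment is best-bit-score local alignment (match +1, mismatch
−1, gap open −5, gap extend −1, both strands) against a user library; ties
break by library order and are logged.

Candidate discovery mirrors the original in-silico screen: both flanks of
an annotated element are located in an outgroup sequence by local
alignment; an accepted candidate needs both flanks on one strand, identity
≥ 0.75 (matches / flank length), and an inter-flank gap shorter than half
the element — the empty-site signature. The two flank hits typically
*overlap* by one TSD length (both claim the single target-site copy), so
colinearity tolerates overlaps up to 25 nt.

## Mapping and branch support

A marker maps to a branch whose clade, restricted to the marker's non-'?'
taxa, equals its present set. '?' cells can leave several nested branches
compatible; the most recent (smallest clade) is reported as supported, the
rest listed — matching the practice of substituting a close relative for a
missing taxon. A marker compatible with no branch is a conflict; it is
reported, never reassigned.

Branch support uses a hard-polytomy null: if the branch were a polytomy,
each of the three local-quartet resolutions would be equally likely, so
with n₁ markers for the branch and n₂ + n₃ for the alternatives,
`p = P(X ≥ n₁)`, `X ~ Binomial(n₁+n₂+n₃, 1/3)`, computed as an exact
integer tail sum (no floating-point summation of binomial terms). This is
a deliberately simple, enumeration-checkable surrogate for the specialised
insertion-marker significance tests in the literature; the interface
(`branch_support_test(n1, n2, n3)`) accepts a drop-in replacement.

## Anatomy

The majority-rule consensus emits a column when more than half the copies
have a residue there, takes the most frequent base, and encodes frequency
ties as IUPAC ambiguity codes (a stated choice; "majority rule" alone does
not fix tie behaviour). Head/tail partitioning aligns tRNA and CR1
libraries locally against the consensus and places the boundary at the
midpoint between the tRNA hit's end and the CR1 hit's start — which is
also the crossover midpoint when the hits overlap; a `min_score` of 20
(≈ 20 identical nt under the default scoring) guards against partitioning
sequences that contain only one component. Diagnostic sites are columns
where all SINE tails agree on a residue and the source CR1 differs;
screening counts copies carrying *all* diagnostic states. RNA motifs are
handled in DNA space (U→T); secondary-structure prediction is out of
scope.

## Divergence landscapes

K2P distances use the closed form with transition fraction P and
transversion fraction Q over columns that survive pairwise deletion of
gaps/ambiguities, after excluding both positions of every CpG dinucleotide
of the consensus (CpG adjacency judged with consensus gap columns
skipped). CpG exclusion is total removal, not down-weighting — the one
variant stated for the original MEGA analysis; uniform rates among sites,
no gamma correction. Saturation (log argument ≤ 0) raises an explicit
`SaturationError` rather than returning NaN; saturated copies are dropped
from landscape bins with a warning and listed in the summary. Outputs are
percent; internal units are substitutions/site.

## Concatenation

Element columns (optionally plus the reference taxon's duplicated 3′ TSD
copy, restoring the empty-site architecture) are removed per locus; flanks
are concatenated in sorted locus order with '?' padding for missing taxa —
'?' rather than '-' so missing data stay distinguishable from indels. TSD
columns are retained by default since published flank supermatrices do not
state their removal; `drop_tsd` covers the other convention. Partition
tables are exported 0-based half-open internally and 1-based inclusive in
RAxML format.

## Numerical and degenerate-input choices

- `evolve_sequence` rejects non-ACGT input naming the offending position;
  distance 0 is an exact identity.
- All randomness flows through `numpy.random.default_rng` seeds; identical
  config + seed gives byte-identical locus sets.
- `detect_tsd` at a sequence boundary warns and returns none.
- `k2p_distance` with zero comparable sites is an error, not 0.
- Empty trees, zero requested loci, duplicate locus ids, ragged
  alignments, and frame-length mismatches all raise immediately.

## Problem sizes

The test suite and the acceptance script run entirely from synthetic data:
100-locus recovery studies on 4-, 8- and 12-taxon trees (150 nt flanks per
side), a 20-seed Dollo/ILS sweep (10 + 6 loci per seed), 1,000-pair
estimator cross-checks, 50-chimera partition studies, and 200-copy
landscapes. These sizes give stable pass/fail behaviour at interactive
runtimes (the full suite in well under a minute of CPU); all counts are
ordinary function arguments and scale up freely.

## Known limitations

- Calling assumes pre-aligned loci with a trustworthy element span
  annotation; it does not compute alignments or discover repeat families
  de novo.
- The polytomy binomial test is a surrogate, not the specialised KKSC
  insertion-significance test.
- The ILS generator draws only the two local-quartet alternatives; deeper
  hemiplasy patterns (spanning several branches) are not simulated.
- CpG exclusion follows the consensus, so hypermutable sites created by a
  copy-specific CpG are not excluded.
- Reproduction of published dataset numbers requires the original
  supplementary files as user-supplied input (see README); they are not
  redistributed.
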