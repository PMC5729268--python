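"""Synthetic marker loci with known insertion history.

Generates the inputs the calling pipeline expects — per-locus alignments of
flanking sequence with a chimeric tRNA/CR1 SINE inserted on a designated
branch of a species tree — together with a truth table, so that every
downstream stage can be tested against known states.

The model: an ancestral flank evolves down the rooted tree under a Kimura
two-parameter (K2P) substitution process (transition/transversion rate ratio
kappa, equal base frequencies, no indels).  On the insertion branch the
element is inserted at the flank midpoint by target-primed reverse
transcription, duplicating the target site of length drawn from
``tsd_length_range``.  Each inserted copy (element plus both TSD copies)
then decays independently by ``copy_divergence`` expected substitutions per
site, emulating post-insertion neutral drift of a dead copy.  With
probability ``ils_probability`` a marker is instead assigned to one of the
two discordant resolutions of the insertion branch's local quartet,
emulating incomplete lineage sorting of an ancestral insertion polymorphism.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

from retromark.markers import LocusAlignment
from retromark.trees import branch_id, clade_of, resolve_branch

__all__ = [
    "SineTemplate", "SimConfig", "SimTruth",
    "evolve_sequence", "make_sine_template", "simulate_locus_set",
    "SYNTH_TRNA_ILE", "SYNTH_TRNA_ASP", "SYNTH_CR1_TAIL", "synthetic_library",
]

_NUC = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(_NUC)}
_MICROSAT_RE = re.compile(r"ATTCT[AG]TG$")

# Synthetic stand-ins for the tRNA-Ile / tRNA-Asp genes and the CR1 3' end
# that seed real SINE families (random sequences with the right lengths and
# the terminal A-T-T-C-T-R-T-G microsatellite; not biological sequences).
SYNTH_TRNA_ILE = "AATTACTACCCAGGTTCTTCTACGCGTCCTATATCCAGACAGTGCTCGGGAAAAGATATTGAGAGTGTAAAG"
SYNTH_TRNA_ASP = "TCTGGAGAGGATTCAAGCTGTTTCTTTGAGCATAGAAACGTGCTGGTGGCGTCACTCCTCCGTCCTAACGGC"
SYNTH_CR1_TAIL = (
    "ACCTTTTACTATGTTGGCGCGCCGCCAACAATACTTCCCTCGTACCGACGGATGCCCCCATGCTGCACTAGC"
    "ATTTATATCAGACCAATTACAGACTCGAGACCATTCTAGCCTCGAAGCCTAGAGCGCTGTGAACCTCACC"
    "ATTCTGTG"
)


@dataclass
class SineTemplate:
    """A chimeric SINE: tRNA-derived head + CR1-derived tail.

    The tail must end with the 8-nt microsatellite A-T-T-C-T-R-T-G (R in
    {A, G}) used for target-primed reverse transcription by the CR1 reverse
    transcriptase.
    """

    head: str
    tail: str
    microsat: str
    name: str = "synthSINE"

    @property
    def sequence(self) -> str:
        return self.head + self.tail

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimConfig:
    """Knobs of the locus simulator.

    flank_length
        nt of flank on each side of the insertion point (default 250, giving
        ~500 columns of flank per locus as in typical presence/absence
        amplicons).
    ts_tv_ratio
        kappa, the transition/transversion *rate* ratio (default 2).
    tsd_length_range
        inclusive [min, max] of the target-site-duplication length; must lie
        within [4, 20].
    ils_probability
        per-marker probability of a discordant (hemiplasious) placement
        (default 0.02, of the order of one marker in 44).
    copy_divergence
        expected substitutions/site applied to every inserted copy
        (default 0.06, matching a young SINE family averaging ~6 % to its
        consensus).
    n_loci_per_branch
        branch id (comma-joined sorted leaf labels, see retromark.trees) ->
        number of loci to insert on that branch.
    reverse_strand
        insert copies in reverse orientation (for negative tests of the
        orientation criterion).
    """

    n_loci_per_branch: dict[str, int]
    seed: int
    flank_length: int = 250
    ts_tv_ratio: float = 2.0
    tsd_length_range: tuple[int, int] = (6, 12)
    ils_probability: float = 0.02
    copy_divergence: float = 0.06
    reverse_strand: bool = False

    def __post_init__(self) -> None:
        if self.flank_length <= 0:
            raise ValueError("flank_length must be > 0")
        if not 0.0 <= self.ils_probability <= 1.0:
            raise ValueError("ils_probability must be in [0, 1]")
        lo, hi = self.tsd_length_range
        if not (4 <= lo <= hi <= 20):
            raise ValueError("tsd_length_range must lie within [4, 20]")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be > 0")
        if self.copy_divergence < 0:
            raise ValueError("copy_divergence must be >= 0")


@dataclass
class SimTruth:
    """Ground truth for one simulated locus."""

    locus_id: str
    insertion_branch: str
    tsd_sequence: str
    per_taxon_state: dict[str, str]
    is_ils: bool = False


# ---------------------------------------------------------------------------
# K2P sequence evolution
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(256, 255, dtype=np.uint8)
    for c, i in _NUC_INDEX.items():
        codes[ord(c)] = i
    enc = codes[arr]
    bad = np.nonzero(enc == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"non-ACGT character {seq[pos]!r} at position {pos}")
    return enc


def _decode(enc: np.ndarray) -> str:
    lut = np.frombuffer(_NUC.encode(), dtype=np.uint8)
    return lut[enc].tobytes().decode()


def _k2p_probs(distance: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after *distance* subs/site."""
    # transition rate a, transversion rate b per target base; a + 2b = d
    bt = distance / (kappa + 2.0)
    at = kappa * bt
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * bt) - 0.5 * np.exp(-2.0 * (at + bt))
    p_tv = 0.25 - 0.25 * np.exp(-4.0 * bt)
    return float(p_ts), float(p_tv)


def evolve_sequence(seq: str, distance: float, kappa: float = 2.0,
                    seed: int | np.random.Generator = 0) -> str:
    """Evolve *seq* by *distance* expected substitutions/site under K2P.

    Per-site substitution probabilities come from the closed-form K2P
    transition matrix with transition/transversion rate ratio *kappa* and
    equal base frequencies, so realised divergence is an unbiased draw around
    the nominal distance.  Deterministic given the seed.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    enc = _encode(seq)
    if distance == 0 or enc.size == 0:
        return seq.upper()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_ts, p_tv = _k2p_probs(distance, kappa)
    u = rng.random(enc.size)
    out = enc.copy()
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
    tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    out[ts_mask] = (enc[ts_mask] + 2) % 4        # A<->G, C<->T
    out[tv1_mask] = (enc[tv1_mask] + 1) % 4      # one transversion partner
    out[tv2_mask] = (enc[tv2_mask] + 3) % 4      # the other
    return _decode(out)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return _decode(rng.integers(0, 4, size=length, dtype=np.uint8))


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def make_sine_template(trna: str, cr1_tail: str, name: str = "synthSINE") -> SineTemplate:
    """Assemble a chimeric SINE template from a tRNA head and a CR1 tail.

    The CR1 tail must terminate in the A-T-T-C-T-R-T-G microsatellite that
    CR1-mobilised elements carry at their very 3' end.
    """
    trna = trna.upper()
    cr1_tail = cr1_tail.upper()
    _encode(trna)
    _encode(cr1_tail)
    m = _MICROSAT_RE.search(cr1_tail)
    if m is None:
        raise ValueError(
            "CR1 tail must end with the ATTCTRTG (R=A/G) terminal microsatellite "
            "required for target-primed reverse transcription"
        )
    return SineTemplate(head=trna, tail=cr1_tail, microsat=m.group(0), name=name)


def synthetic_library() -> dict[str, str]:
    """Reference library of the synthetic stand-in sources (tRNAs, CR1 tail)."""
    return {
        "tRNA-Ile_synth": SYNTH_TRNA_ILE,
        "tRNA-Asp_synth": SYNTH_TRNA_ASP,
        "CR1-X1_synth_3end": SYNTH_CR1_TAIL,
    }


# ---------------------------------------------------------------------------
# locus simulation
# ---------------------------------------------------------------------------

def _evolve_down_tree(tree: dendropy.Tree, root_seq: str, kappa: float,
                      rng: np.random.Generator) -> dict[dendropy.Node, str]:
    """Sequence state at every node, evolving along each edge independently."""
    states: dict[dendropy.Node, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_seq
        else:
            d = node.edge.length or 0.0
            states[node] = evolve_sequence(states[node.parent_node], d, kappa, rng)
    return states


def _ils_present_sets(node: dendropy.Node) -> list[frozenset[str]] | None:
    """The two discordant resolutions of the branch's local quartet.

    For an internal branch with child clades A, B and sibling clade C the
    concordant marker set is A+B; the hemiplasious alternatives are A+C and
    B+C.  Returns None when the branch has no local quartet (leaf branch,
    root child without a sibling, non-bifurcating node).
    """
    parent = node.parent_node
    if parent is None or len(node.child_nodes()) != 2:
        return None
    siblings = [c for c in parent.child_nodes() if c is not node]
    if len(siblings) != 1:
        return None
    a, b = (clade_of(c) for c in node.child_nodes())
    c = clade_of(siblings[0])
    return [a | c, b | c]


def simulate_locus_set(tree: dendropy.Tree, template: SineTemplate,
                       cfg: SimConfig) -> tuple[list[LocusAlignment], list[SimTruth]]:
    """Simulate presence/absence marker loci on a species tree.

    Returns column-consistent per-locus alignments (the element plus the
    duplicated TSD copy appear as gap columns in absence taxa) and one truth
    record per locus.  Byte-identical output for identical config and seed.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if not leaves:
        raise ValueError("empty tree")
    total = sum(cfg.n_loci_per_branch.values())
    if total <= 0:
        raise ValueError("zero loci requested")
    branches = {b: resolve_branch(tree, b) for b in cfg.n_loci_per_branch}

    rng = np.random.default_rng(cfg.seed)
    elem = template.sequence
    if cfg.reverse_strand:
        comp = str.maketrans("ACGT", "TGCA")
        elem = elem.translate(comp)[::-1]

    loci: list[LocusAlignment] = []
    truths: list[SimTruth] = []
    i = 0
    for branch_spec in sorted(cfg.n_loci_per_branch):
        node = branches[branch_spec]
        for _ in range(cfg.n_loci_per_branch[branch_spec]):
            locus_id = f"L{i:04d}"
            i += 1
            m = cfg.flank_length
            root_flank = _random_sequence(2 * m, rng)
            states = _evolve_down_tree(tree, root_flank, cfg.ts_tv_ratio, rng)

            tsd_len = int(rng.integers(cfg.tsd_length_range[0],
                                       cfg.tsd_length_range[1] + 1))
            target = states[node][m:m + tsd_len]

            present: frozenset[str] = clade_of(node)
            is_ils = False
            if cfg.ils_probability > 0 and rng.random() < cfg.ils_probability:
                alts = _ils_present_sets(node)
                if alts is not None:
                    present = alts[int(rng.integers(2))]
                    is_ils = True

            unit = target + elem + target  # both TSD copies decay with the copy
            rows: dict[str, str] = {}
            for leaf in tree.leaf_node_iter():
                label = leaf.taxon.label
                flank = states[leaf]
                if label in present:
                    decayed = evolve_sequence(unit, cfg.copy_divergence,
                                              cfg.ts_tv_ratio, rng)
                    rows[label] = flank[:m] + decayed + flank[m + tsd_len:]
                else:
                    rows[label] = (flank[:m + tsd_len]
                                   + "-" * (len(elem) + tsd_len)
                                   + flank[m + tsd_len:])
            span = (m + tsd_len, m + tsd_len + len(elem))
            ref = next(l for l in leaves if l in present)
            loci.append(LocusAlignment(locus_id, rows, span, ref))
            truths.append(SimTruth(
                locus_id=locus_id,
                insertion_branch=branch_id(node),
                tsd_sequence=target,
                per_taxon_state={l: ("present" if l in present else "absent")
                                 for l in leaves},
                is_ils=is_ils,
            ))
    return loci, truths
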