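"""SINE family anatomy: consensus, chimeric head/tail partition, diagnostics.

The SINE families handled here are chimeras: a tRNA-derived head (carrying
the pol III promoter boxes) fused to the 3' end of a CR1 LINE (carrying the
reverse-transcriptase binding site and a terminal 8-nt microsatellite).
Given a majority-rule consensus of family copies and reference libraries of
tRNA genes and CR1 3' ends, the family model records where the head stops
and the tail starts, which sources they derive from, and which tail
positions diagnostically separate the SINE from its source CR1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

from retromark.markers import make_aligner, _best_alignment

__all__ = [
    "SineFamilyModel", "DiagnosticSite", "MicrosatMatch",
    "majority_consensus", "partition_sine", "diagnostic_sites",
    "screen_copies", "check_terminal_microsat",
]

_GAPS = frozenset("-?.")

# tied-base sets -> IUPAC ambiguity code
_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}

_MICROSAT = re.compile(r"ATTCT[AG]TG")


class DiagnosticSite(NamedTuple):
    """A column where all SINE tails agree and the source CR1 differs."""

    position: int
    sine_state: str
    cr1_state: str


@dataclass
class MicrosatMatch:
    """Outcome of the terminal-microsatellite check; truthy when found."""

    found: bool
    position: int | None = None

    def __bool__(self) -> bool:
        return self.found


@dataclass
class SineFamilyModel:
    """Consensus-level description of one SINE family."""

    name: str
    consensus: str
    head_span: tuple[int, int]
    tail_span: tuple[int, int]
    head_source: str
    tail_source: str
    diagnostic_sites: list[DiagnosticSite] = field(default_factory=list)
    microsat_present: bool = False


def majority_consensus(copies: list[str] | dict[str, str]) -> str:
    """Majority-rule consensus of aligned family copies.

    Per column the most frequent non-gap base wins; the column is emitted
    only when more than half of the copies have a non-gap character there;
    frequency ties become the IUPAC ambiguity code of the tied bases.
    """
    if isinstance(copies, dict):
        copies = list(copies.values())
    if not copies:
        raise ValueError("empty alignment")
    if len(copies) < 2:
        raise ValueError("need >= 2 aligned copies for a consensus")
    if len({len(c) for c in copies}) != 1:
        raise ValueError("copies differ in aligned length")
    n = len(copies)
    out: list[str] = []
    for col in zip(*[c.upper() for c in copies]):
        residues = [c for c in col if c not in _GAPS]
        if 2 * len(residues) <= n:
            continue
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        top = max(counts.values())
        winners = frozenset(c for c, k in counts.items() if k == top)
        if len(winners) == 1:
            out.append(next(iter(winners)))
        else:
            out.append(_IUPAC.get(winners, "N"))
    return "".join(out)


def partition_sine(consensus: str, trna_lib: dict[str, str],
                   cr1_lib: dict[str, str],
                   min_score: float = 20.0) -> SineFamilyModel:
    """Partition a SINE consensus into tRNA-derived head and CR1-derived tail.

    Each library is locally aligned against the consensus (match +1,
    mismatch -1, gap open -5, gap extend -1, both strands); the boundary is
    the midpoint between the end of the best tRNA hit and the start of the
    best CR1 hit (which is also the crossover midpoint when they overlap).
    Raises ValueError("unpartitionable") when either library has no hit
    scoring >= *min_score*.
    """
    if not trna_lib or not cr1_lib:
        raise ValueError("reference libraries must be non-empty")
    aligner = make_aligner()

    def top_hit(lib: dict[str, str]) -> tuple[str, tuple[int, int]] | None:
        best: tuple[float, str, tuple[int, int]] | None = None
        for name, ref in lib.items():
            aln = _best_alignment(consensus, ref, aligner)
            if aln is None:
                continue
            # span of the hit on the consensus (the aligner's query)
            blocks = aln.aligned[1]
            span = (int(blocks[0][0]), int(blocks[-1][1]))
            if best is None or aln.score > best[0]:
                best = (float(aln.score), name, span)
        if best is None or best[0] < min_score:
            return None
        return best[1], best[2]

    head = top_hit(trna_lib)
    tail = top_hit(cr1_lib)
    if head is None or tail is None:
        missing = "tRNA" if head is None else "CR1"
        raise ValueError(f"unpartitionable: no {missing} hit above score {min_score}")
    head_name, (h_start, h_end) = head
    tail_name, (t_start, t_end) = tail
    if t_end <= h_start:
        raise ValueError("unpartitionable: CR1 hit precedes the tRNA hit")
    boundary = (h_end + t_start) // 2
    boundary = max(h_start + 1, min(boundary, t_end - 1))
    micro = check_terminal_microsat(consensus) if len(consensus) >= 8 else MicrosatMatch(False)
    return SineFamilyModel(
        name="sine_family",
        consensus=consensus,
        head_span=(h_start, boundary),
        tail_span=(boundary, t_end),
        head_source=head_name,
        tail_source=tail_name,
        microsat_present=bool(micro),
    )


def diagnostic_sites(tails: list[str] | dict[str, str],
                     cr1_ref: str) -> list[DiagnosticSite]:
    """Columns separating a set of SINE tails from the source CR1 3' end.

    All sequences must be in one alignment frame.  A column is diagnostic
    when every tail shares one non-gap state and the CR1 reference carries a
    different, non-gap state.
    """
    if isinstance(tails, dict):
        tails = list(tails.values())
    if len(tails) < 1:
        raise ValueError("need at least one SINE tail")
    if any(len(t) != len(cr1_ref) for t in tails):
        raise ValueError("tails and CR1 reference differ in aligned length")
    sites: list[DiagnosticSite] = []
    for pos, (ref_c, *tail_col) in enumerate(zip(cr1_ref.upper(),
                                                 *[t.upper() for t in tails])):
        states = set(tail_col)
        if len(states) != 1:
            continue
        (state,) = states
        if state in _GAPS or ref_c in _GAPS:
            continue
        if state != ref_c:
            sites.append(DiagnosticSite(pos, state, ref_c))
    return sites


def screen_copies(copies: dict[str, str] | list[str],
                  sites: list[DiagnosticSite]) -> tuple[int, dict[str, list[int]]]:
    """Count aligned copies carrying ALL diagnostic states.

    Returns the count and a per-copy report of which site positions matched.
    """
    if isinstance(copies, list):
        copies = {f"copy{i}": s for i, s in enumerate(copies)}
    report: dict[str, list[int]] = {}
    count = 0
    for name, seq in copies.items():
        for site in sites:
            if site.position >= len(seq):
                raise ValueError(f"site {site.position} outside copy {name!r}")
        matched = [s.position for s in sites
                   if seq[s.position].upper() == s.sine_state]
        report[name] = matched
        if len(matched) == len(sites):
            count += 1
    return count, report


def check_terminal_microsat(seq: str) -> MicrosatMatch:
    """Check for the terminal CR1 microsatellite A-T-T-C-T-R-T-G (R = A/G).

    RNA input is accepted (U is transliterated to T); the match must cover
    the last 8 nt of the sequence.
    """
    if len(seq) < 8:
        raise ValueError("sequence shorter than the 8-nt motif")
    dna = seq.upper().replace("U", "T")
    if _MICROSAT.fullmatch(dna[-8:]):
        return MicrosatMatch(True, len(seq) - 8)
    return MicrosatMatch(False)
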