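"""CpG-excluded Kimura 2-parameter divergence and family landscapes.

The age structure of a repeat family is read from the divergence of its
copies to the family consensus: young families pile up near 0 %, dead ones
drift outward.  Distances use the Kimura two-parameter estimator

    d = -1/2 ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

with transition fraction P and transversion fraction Q, uniform rates among
sites and pairwise deletion of gaps/missing data.  CpG dinucleotides in the
consensus are hypermutable (methyl-C deamination) and would inflate the
clock, so both positions of every consensus CpG are excluded before
counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "DivergenceEstimate", "LandscapeBin", "SaturationError",
    "k2p_distance", "family_landscape", "cpg_columns",
]

_VALID = frozenset("ACGT")
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))


class SaturationError(ValueError):
    """The K2P logarithm argument is non-positive: distance undefined."""


@dataclass
class DivergenceEstimate:
    p_transitions: float
    q_transversions: float
    distance: float
    n_sites: int


@dataclass
class LandscapeBin:
    bin_lower: float  # percent divergence, inclusive lower edge
    bin_width: float  # percent
    copy_count: int


def cpg_columns(consensus: str) -> set[int]:
    """Alignment columns covered by CpG dinucleotides of the consensus.

    Adjacency is judged on the consensus with gap columns skipped: a C
    followed (at the next non-gap column) by a G marks both columns for
    exclusion.  Overlapping CpGs (e.g. CGCG) simply union.
    """
    cols: set[int] = set()
    seq = consensus.upper()
    nongap = [i for i, c in enumerate(seq) if c not in "-?."]
    for a, b in zip(nongap, nongap[1:]):
        if seq[a] == "C" and seq[b] == "G":
            cols.update((a, b))
    return cols


def k2p_distance(a: str, b: str,
                 exclude_cpg_in: str | None = None) -> DivergenceEstimate:
    """Kimura 2-parameter distance between two aligned sequences.

    Columns where either sequence has a gap or ambiguity are deleted
    pairwise.  When *exclude_cpg_in* is given (a consensus in the same
    alignment frame), both positions of each of its CpG dinucleotides are
    excluded as well.  Raises SaturationError when the estimator is
    undefined, and ValueError when no comparable sites remain.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in aligned length")
    excluded: set[int] = set()
    if exclude_cpg_in is not None:
        if len(exclude_cpg_in) != len(a):
            raise ValueError("consensus not in the same alignment frame")
        excluded = cpg_columns(exclude_cpg_in)
    n = ts = tv = 0
    au, bu = a.upper(), b.upper()
    for i, (x, y) in enumerate(zip(au, bu)):
        if i in excluded or x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites after exclusions")
    p, q = ts / n, tv / n
    arg = (1.0 - 2.0 * p - q) * math.sqrt(1.0 - 2.0 * q) if q < 0.5 else 0.0
    if arg <= 0.0:
        raise SaturationError(
            f"saturated: P={p:.3f}, Q={q:.3f} leave no defined K2P distance")
    return DivergenceEstimate(p, q, -0.5 * math.log(arg), n)


def family_landscape(copies: dict[str, str], consensus: str,
                     bin_width: float = 1.0
                     ) -> tuple[list[LandscapeBin], dict]:
    """Divergence landscape of a repeat family.

    Each aligned copy is compared to the consensus by CpG-excluded K2P
    distance; distances are reported in percent and histogrammed in
    contiguous bins of *bin_width* percent starting at 0.  Saturated copies
    are dropped from the bins with a warning and listed in the summary.

    Returns ``(bins, summary)`` with summary keys ``mean``, ``min``, ``max``
    (percent), ``n_copies``, ``per_copy`` (name -> DivergenceEstimate) and
    ``saturated`` (list of names).
    """
    if not copies:
        raise ValueError("no copies given")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    per_copy: dict[str, DivergenceEstimate] = {}
    saturated: list[str] = []
    for name, seq in copies.items():
        try:
            per_copy[name] = k2p_distance(seq, consensus, exclude_cpg_in=consensus)
        except SaturationError:
            warnings.warn(f"copy {name!r} saturated; dropped from landscape",
                          stacklevel=2)
            saturated.append(name)
    pcts = [100.0 * est.distance for est in per_copy.values()]
    bins: list[LandscapeBin] = []
    if pcts:
        n_bins = max(1, math.floor(max(pcts) / bin_width) + 1)
        counts = [0] * n_bins
        for v in pcts:
            counts[min(int(v / bin_width), n_bins - 1)] += 1
        bins = [LandscapeBin(i * bin_width, bin_width, c)
                for i, c in enumerate(counts)]
    summary = {
        "mean": sum(pcts) / len(pcts) if pcts else math.nan,
        "min": min(pcts) if pcts else math.nan,
        "max": max(pcts) if pcts else math.nan,
        "n_copies": len(per_copy),
        "per_copy": per_copy,
        "saturated": saturated,
    }
    return bins, summary
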