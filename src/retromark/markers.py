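"""Presence/absence marker discovery and per-taxon insertion calling.

A marker locus is an orthologous genomic region in which some taxa carry a
retroposon insertion and others show the pristine empty site.  Such loci are
near-homoplasy-free phylogenetic characters, but only when called strictly:
a taxon is scored *present* only if its copy sits at the identical insertion
point, in the identical orientation, belongs to the identical element
subtype, and (when detectable) carries an identical target-site duplication
(TSD) as the reference taxon; a taxon is scored *absent* only if the element
span is empty and the flanks are contiguous.  Anything else is *ambiguous*
and never counts for or against a marker.

Coordinates are 0-based, half-open, in alignment-column space unless a
function says otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-?")
MISSING_CHARS = frozenset("-?Nn")

#: reason codes attached to ambiguous calls / invalid markers
REASON_PARTIAL = "partial_element"
REASON_JUNCTION = "shifted_junction"
REASON_SUBTYPE = "subtype_mismatch"
REASON_ORIENTATION = "orientation_flip"
REASON_TSD = "tsd_mismatch"
REASON_MISSING = "missing_sequence"
REASON_FLANK = "flank_discontiguous"


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class LocusAlignment:
    """One marker locus: aligned taxon rows plus the annotated element span.

    Parameters
    ----------
    locus_id
        Unique locus label.
    rows
        Mapping taxon -> aligned sequence; gaps ``-``, missing data ``?``.
    element_span
        ``[start, end)`` of the inserted element in alignment columns,
        annotated on ``ref_taxon``.
    ref_taxon
        The taxon whose copy defined the span; its row must be essentially
        ungapped (< 10 % gaps) inside the span.
    """

    locus_id: str
    rows: dict[str, str]
    element_span: tuple[int, int]
    ref_taxon: str

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.locus_id}: no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"{self.locus_id}: rows differ in aligned length")
        (self.n_columns,) = lengths
        s, e = self.element_span
        if not (0 <= s < e <= self.n_columns):
            raise ValueError(
                f"{self.locus_id}: element_span {self.element_span} outside "
                f"[0, {self.n_columns})"
            )
        if self.ref_taxon not in self.rows:
            raise ValueError(f"{self.locus_id}: ref_taxon {self.ref_taxon!r} has no row")
        ref_seg = self.rows[self.ref_taxon][s:e]
        gap_frac = sum(c in GAP_CHARS for c in ref_seg) / len(ref_seg)
        if gap_frac >= 0.10:
            raise ValueError(
                f"{self.locus_id}: ref_taxon row is {gap_frac:.0%} gap inside the "
                "element span"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)


@dataclass
class InsertionCall:
    """Per-taxon state at one locus."""

    taxon: str
    state: str  # "present" | "absent" | "ambiguous"
    left_junction: int | None = None
    right_junction: int | None = None
    tsd: str | None = None
    orientation: str | None = None  # "forward" | "reverse"
    subtype: str | None = None
    reasons: list[str] = field(default_factory=list)


@dataclass
class MarkerRecord:
    """Validation verdict for one locus."""

    locus_id: str
    calls: list[InsertionCall]
    valid: bool
    re_class: str
    failure_reasons: list[str] = field(default_factory=list)


@dataclass
class CandidateLocus:
    """Result of screening one annotated element against an outgroup."""

    element_index: int
    element_span: tuple[int, int]
    accepted: bool
    reason: str | None = None
    left_hit: tuple[int, int] | None = None
    right_hit: tuple[int, int] | None = None
    interflank_gap: int | None = None


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------

def ungap(row: str) -> str:
    return "".join(c for c in row if c not in GAP_CHARS)


def _col_to_ungapped(row: str, col: int) -> int:
    """Number of non-gap characters strictly before alignment column *col*."""
    return sum(1 for c in row[:col] if c not in GAP_CHARS)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def make_aligner(match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    """Local nucleotide aligner with the package's standard scoring."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _best_alignment(query: str, target: str, aligner: Align.PairwiseAligner):
    """Best local alignment, or None when nothing aligns."""
    if not query or not target:
        return None
    alignments = aligner.align(target, query)
    try:
        return alignments[0]
    except IndexError:
        return None


def _alignment_identity(alignment, query_len: int) -> float:
    """Matches in the local alignment divided by full query length."""
    target = alignment.target
    query = alignment.query
    matches = 0
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        matches += sum(a == b for a, b in zip(target[ts:te], query[qs:qe]))
    return matches / query_len


def best_library_hit(seq: str, library: dict[str, str],
                     aligner: Align.PairwiseAligner | None = None
                     ) -> tuple[str, float, str] | None:
    """Best-scoring local hit of *seq* against a reference element library.

    Both strands are tried; ties are broken by library order (first wins,
    logged at DEBUG level).  Returns ``(name, score, strand)`` or None for an
    empty library / unalignable sequence.
    """
    if aligner is None:
        aligner = make_aligner()
    best: tuple[str, float, str] | None = None
    for name, ref in library.items():
        for strand, s in (("forward", seq), ("reverse", _revcomp(seq))):
            aln = _best_alignment(s, ref, aligner)
            if aln is None:
                continue
            score = float(aln.score)
            if best is None or score > best[1]:
                best = (name, score, strand)
            elif score == best[1] and (name, strand) != (best[0], best[2]):
                logger.debug("library tie at score %.1f: kept %s/%s over %s/%s",
                             score, best[0], best[2], name, strand)
    return best


# ---------------------------------------------------------------------------
# TSD detection
# ---------------------------------------------------------------------------

def detect_tsd(row: str, element_start: int, element_end: int,
               max_len: int = 20, min_len: int = 4) -> str | None:
    """Longest exact direct repeat flanking an element.

    Target-primed reverse transcription duplicates the target site, leaving
    the same short string immediately 5' of the element and again starting at
    its 3' junction.  Searches for the longest exact string ``s`` with
    ``min_len <= len(s) <= max_len`` such that *row* ends with ``s`` at
    ``element_start`` and ``s`` begins at ``element_end``.

    *row* is ungapped; positions are 0-based half-open on it.
    """
    if not (0 <= element_start <= element_end <= len(row)):
        raise ValueError("element positions outside the sequence")
    if element_start == 0 or element_end == len(row):
        warnings.warn(
            "element touches the sequence boundary; TSD undetectable",
            stacklevel=2,
        )
        return None
    limit = min(max_len, element_start, len(row) - element_end)
    for length in range(limit, min_len - 1, -1):
        left = row[element_start - length:element_start]
        right = row[element_end:element_end + length]
        if left == right:
            return left
    return None


# ---------------------------------------------------------------------------
# per-taxon classification
# ---------------------------------------------------------------------------

def _row_element_info(row: str, span: tuple[int, int],
                      max_tsd: int, min_tsd: int) -> dict:
    """Junctions, ungapped element sequence and TSD for one present-like row."""
    s, e = span
    cols = [c for c in range(s, e) if row[c] not in GAP_CHARS]
    left = cols[0]
    right = cols[-1] + 1
    u_start = _col_to_ungapped(row, left)
    u_end = _col_to_ungapped(row, right)
    u_row = ungap(row)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tsd = detect_tsd(u_row, u_start, u_end, max_len=max_tsd, min_len=min_tsd)
    return {
        "left_junction": left,
        "right_junction": right,
        "element_seq": u_row[u_start:u_end],
        "tsd": tsd,
    }


class _RefProfile:
    """Reference-taxon annotation computed once per locus."""

    def __init__(self, locus: LocusAlignment, library: dict[str, str],
                 aligner: Align.PairwiseAligner, max_tsd: int, min_tsd: int):
        info = _row_element_info(locus.rows[locus.ref_taxon], locus.element_span,
                                 max_tsd, min_tsd)
        self.left_junction = info["left_junction"]
        self.right_junction = info["right_junction"]
        self.tsd = info["tsd"]
        hit = best_library_hit(info["element_seq"], library, aligner)
        self.subtype = hit[0] if hit else None
        self.orientation = hit[2] if hit else None


def _classify_row(locus: LocusAlignment, taxon: str, ref: _RefProfile,
                  library: dict[str, str], aligner: Align.PairwiseAligner,
                  junction_tol: int, max_tsd: int, min_tsd: int,
                  flank_window: int) -> InsertionCall:
    row = locus.rows[taxon]
    s, e = locus.element_span
    if all(c in MISSING_CHARS for c in row):
        return InsertionCall(taxon, "ambiguous", reasons=[REASON_MISSING])

    seg = row[s:e]
    gap_frac = sum(c in GAP_CHARS for c in seg) / len(seg)

    if gap_frac <= 0.10:
        reasons: list[str] = []
        info = _row_element_info(row, locus.element_span, max_tsd, min_tsd)
        if (abs(info["left_junction"] - ref.left_junction) > junction_tol
                or abs(info["right_junction"] - ref.right_junction) > junction_tol):
            reasons.append(REASON_JUNCTION)
        hit = best_library_hit(info["element_seq"], library, aligner)
        subtype = hit[0] if hit else None
        orientation = hit[2] if hit else None
        if subtype != ref.subtype:
            reasons.append(REASON_SUBTYPE)
        elif orientation != ref.orientation:
            reasons.append(REASON_ORIENTATION)
        # TSD criterion applies only when detected on both sides ("if present")
        if info["tsd"] is not None and ref.tsd is not None and info["tsd"] != ref.tsd:
            reasons.append(REASON_TSD)
        if reasons:
            return InsertionCall(taxon, "ambiguous",
                                 left_junction=info["left_junction"],
                                 right_junction=info["right_junction"],
                                 tsd=info["tsd"], orientation=orientation,
                                 subtype=subtype, reasons=reasons)
        return InsertionCall(taxon, "present",
                             left_junction=info["left_junction"],
                             right_junction=info["right_junction"],
                             tsd=info["tsd"], orientation=orientation,
                             subtype=subtype)

    if gap_frac >= 0.90:
        # absence additionally requires contiguous flanks around the empty
        # site; the gap block may extend past the span (duplicated TSD
        # columns are gaps too in absence rows), so widen to the maximal gap
        # run containing the span before windowing
        lo_edge, hi_edge = s, e
        while lo_edge > 0 and row[lo_edge - 1] in GAP_CHARS:
            lo_edge -= 1
        while hi_edge < len(row) and row[hi_edge] in GAP_CHARS:
            hi_edge += 1
        for lo, hi in ((max(0, lo_edge - flank_window), lo_edge),
                       (hi_edge, min(len(row), hi_edge + flank_window))):
            window = row[lo:hi]
            if window and sum(c not in GAP_CHARS for c in window) / len(window) < 0.5:
                return InsertionCall(taxon, "ambiguous", reasons=[REASON_FLANK])
        return InsertionCall(taxon, "absent")

    return InsertionCall(taxon, "ambiguous", reasons=[REASON_PARTIAL])


def classify_taxon(locus: LocusAlignment, taxon: str, library: dict[str, str],
                   junction_tol: int = 2, max_tsd: int = 20, min_tsd: int = 4,
                   flank_window: int = 10) -> InsertionCall:
    """Call the presence/absence state of one taxon at one locus.

    *present* requires the element span to be occupied (<= 10 % gaps), both
    junctions within ``junction_tol`` columns of the reference taxon's, the
    best library hit to agree in subtype and orientation with the reference,
    and — when detected on both rows — an identical TSD.  *absent* requires
    the span to be >= 90 % gap with contiguous flanks.  Everything else is
    *ambiguous*, with reason codes.
    """
    if taxon not in locus.rows:
        raise KeyError(f"taxon {taxon!r} not in locus {locus.locus_id}")
    aligner = make_aligner()
    ref = _RefProfile(locus, library, aligner, max_tsd, min_tsd)
    return _classify_row(locus, taxon, ref, library, aligner,
                         junction_tol, max_tsd, min_tsd, flank_window)


def call_locus(locus: LocusAlignment, library: dict[str, str],
               junction_tol: int = 2, max_tsd: int = 20, min_tsd: int = 4,
               flank_window: int = 10) -> list[InsertionCall]:
    """Classify every taxon of a locus (reference profile computed once)."""
    aligner = make_aligner()
    ref = _RefProfile(locus, library, aligner, max_tsd, min_tsd)
    return [
        _classify_row(locus, taxon, ref, library, aligner,
                      junction_tol, max_tsd, min_tsd, flank_window)
        for taxon in locus.rows
    ]


# ---------------------------------------------------------------------------
# marker validation
# ---------------------------------------------------------------------------

_RE_CLASS_KEYS = (
    ("TguSINE1", "SINE-TguSINE1"),
    ("PittSINE", "SINE-PittSINE"),
    ("CR1", "CR1"),
    ("LTR", "LTR"),
    ("ERV", "LTR"),
)


def re_class_of(subtype: str | None) -> str:
    """Map a library sequence name onto a coarse retroposon class."""
    if subtype:
        for key, cls in _RE_CLASS_KEYS:
            if key.lower() in subtype.lower():
                return cls
    return "other"


#: reasons that contradict a shared-insertion criterion and poison the locus
VIOLATION_REASONS = frozenset(
    {REASON_JUNCTION, REASON_SUBTYPE, REASON_ORIENTATION, REASON_TSD})
#: reasons that merely mean "no usable data for this taxon" ('?' cell)
BENIGN_REASONS = frozenset({REASON_MISSING, REASON_PARTIAL, REASON_FLANK})


def validate_marker(locus: LocusAlignment, calls: list[InsertionCall]) -> MarkerRecord:
    """Decide whether a locus is a phylogenetically reliable marker.

    Valid means: at least one present call, at least one clear absence, and
    no call violating any of the shared-insertion criteria (insertion point,
    orientation, subtype, TSD).  A criterion violation anywhere poisons the
    whole locus — a copy at the right spot but in the wrong orientation or
    of the wrong subtype is evidence of an independent insertion, not of
    missing data.  Taxa that are ambiguous for benign reasons (missing or
    partial sequence, discontiguous flanks) never invalidate a marker; they
    become '?' cells in the matrix.
    """
    if len(calls) < 3:
        raise ValueError(f"{locus.locus_id}: need >= 3 called taxa, got {len(calls)}")
    reasons: list[str] = []
    n_present = sum(c.state == "present" for c in calls)
    n_absent = sum(c.state == "absent" for c in calls)
    if all(c.state == "ambiguous" for c in calls):
        reasons.append("uninformative")
    else:
        if n_present == 0:
            reasons.append("no_presence")
        if n_absent == 0:
            reasons.append("no_absence")
    for c in calls:
        reasons.extend(f"{c.taxon}:{r}" for r in c.reasons
                       if r in VIOLATION_REASONS)
    ref_call = next((c for c in calls if c.taxon == locus.ref_taxon), None)
    re_class = re_class_of(ref_call.subtype if ref_call else None)
    return MarkerRecord(locus.locus_id, calls, valid=not reasons,
                        re_class=re_class, failure_reasons=reasons)


# ---------------------------------------------------------------------------
# candidate discovery
# ---------------------------------------------------------------------------

def discover_candidates(ingroup_seq: str,
                        elements: list[tuple[int, int]],
                        outgroup_seq: str,
                        flank_len: int = 300,
                        min_flank_identity: float = 0.75,
                        max_overlap: int = 25) -> list[CandidateLocus]:
    """Screen annotated elements for putative presence/absence loci.

    For each annotated element ``[start, end)`` in *ingroup_seq*, the two
    flanks of ``flank_len`` nt are located in *outgroup_seq* by local
    alignment.  An element becomes an accepted candidate when both flanks map
    co-linearly on the same strand with identity >= *min_flank_identity* and
    the outgroup gap between them is shorter than half the element length —
    the signature of an empty orthologous site.  Rejected elements are
    returned too, with a reason code (``flank_unmapped``, ``strand_mismatch``,
    ``not_colinear``, ``site_occupied``).
    """
    aligner = make_aligner()
    out: list[CandidateLocus] = []
    rc_out = _revcomp(outgroup_seq)
    n_out = len(outgroup_seq)

    def locate(query: str) -> tuple[str, float, int, int] | None:
        best = None
        for strand, target in (("forward", outgroup_seq), ("reverse", rc_out)):
            aln = _best_alignment(query, target, aligner)
            if aln is None:
                continue
            ident = _alignment_identity(aln, len(query))
            blocks = aln.aligned[0]
            t_start, t_end = int(blocks[0][0]), int(blocks[-1][1])
            if strand == "reverse":
                t_start, t_end = n_out - t_end, n_out - t_start
            if best is None or aln.score > best[4]:
                best = (strand, ident, t_start, t_end, aln.score)
        if best is None:
            return None
        return best[:4]

    for idx, (e_start, e_end) in enumerate(elements):
        if not (0 <= e_start < e_end <= len(ingroup_seq)):
            raise ValueError(f"element {idx}: span outside ingroup sequence")
        left = ingroup_seq[max(0, e_start - flank_len):e_start]
        right = ingroup_seq[e_end:e_end + flank_len]
        lh = locate(left) if left else None
        rh = locate(right) if right else None
        if (lh is None or rh is None
                or lh[1] < min_flank_identity or rh[1] < min_flank_identity):
            out.append(CandidateLocus(idx, (e_start, e_end), False, "flank_unmapped"))
            continue
        if lh[0] != rh[0]:
            out.append(CandidateLocus(idx, (e_start, e_end), False, "strand_mismatch"))
            continue
        if lh[0] == "reverse":
            lh, rh = rh, lh  # left flank lies downstream on the minus strand
        # at an empty site both flank hits claim the single target-site copy,
        # so they may overlap by up to one TSD length
        if lh[3] - rh[2] > max_overlap:
            out.append(CandidateLocus(idx, (e_start, e_end), False, "not_colinear",
                                      left_hit=lh[2:4], right_hit=rh[2:4]))
            continue
        gap = rh[2] - lh[3]  # signed; negative = TSD-driven overlap
        if gap >= (e_end - e_start) / 2:
            out.append(CandidateLocus(idx, (e_start, e_end), False, "site_occupied",
                                      left_hit=lh[2:4], right_hit=rh[2:4],
                                      interflank_gap=gap))
            continue
        out.append(CandidateLocus(idx, (e_start, e_end), True,
                                  left_hit=lh[2:4], right_hit=rh[2:4],
                                  interflank_gap=gap))
    return out
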