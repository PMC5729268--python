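"""Flank stripping and supermatrix concatenation for external tree inference.

The retroposon itself is phylogenetically uninformative sequence shared only
by present taxa; the flanks are ordinary orthologous sequence present in all
taxa.  Stripping the element columns (optionally also the duplicated TSD
copy) from every marker alignment and concatenating the flanks yields a
multilocus supermatrix whose ML tree is independent of the presence/absence
characters mapped on it.
"""

from __future__ import annotations

from dataclasses import dataclass

from retromark.markers import GAP_CHARS, LocusAlignment, detect_tsd, ungap, \
    _col_to_ungapped

__all__ = [
    "FlankAlignment", "Supermatrix", "strip_elements", "concatenate",
    "write_supermatrix_fasta", "write_phylip", "write_partitions",
]


@dataclass
class FlankAlignment:
    """Element-free alignment of one locus."""

    locus_id: str
    rows: dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class Supermatrix:
    """Concatenated flank alignments with a partition table.

    Partitions are ``(locus_id, start, end)``, 0-based half-open on the
    concatenated columns, non-overlapping, ordered and covering.  Taxa
    missing from a locus are padded with '?'.
    """

    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))


def strip_elements(locus: LocusAlignment, drop_tsd: bool = False) -> FlankAlignment:
    """Remove the element columns (and optionally the duplicated TSD copy).

    With ``drop_tsd`` the columns of the reference taxon's 3' TSD copy (the
    duplicate created at insertion) are removed too, restoring the
    empty-site architecture with a single copy of the target site.  Row
    order is preserved.
    """
    s, e = locus.element_span
    drop = set(range(s, e))
    if drop_tsd:
        ref_row = locus.rows[locus.ref_taxon]
        u_row = ungap(ref_row)
        u_start = _col_to_ungapped(ref_row, s)
        u_end = _col_to_ungapped(ref_row, e)
        tsd = detect_tsd(u_row, u_start, u_end)
        if tsd is not None:
            # columns holding ungapped positions [u_end, u_end + len(tsd))
            want = set(range(u_end, u_end + len(tsd)))
            u = 0
            for col, ch in enumerate(ref_row):
                if ch not in GAP_CHARS:
                    if u in want:
                        drop.add(col)
                    u += 1
    keep = [c for c in range(locus.n_columns) if c not in drop]
    if not keep:
        raise ValueError(f"{locus.locus_id}: no flanks left after stripping")
    rows = {taxon: "".join(row[c] for c in keep)
            for taxon, row in locus.rows.items()}
    return FlankAlignment(locus.locus_id, rows)


def concatenate(loci: list[FlankAlignment]) -> Supermatrix:
    """Concatenate flank alignments into a supermatrix.

    Loci are ordered by locus_id; the taxon set is the union over loci, with
    missing taxa padded by '?' so missing data stay distinguishable from
    indels.
    """
    if not loci:
        raise ValueError("no loci to concatenate")
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus ids")
    ordered = sorted(loci, key=lambda l: l.locus_id)
    taxa: list[str] = []
    for l in ordered:
        for t in l.rows:
            if t not in taxa:
                taxa.append(t)
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    for l in ordered:
        width = l.n_columns
        if any(len(r) != width for r in l.rows.values()):
            raise ValueError(f"{l.locus_id}: ragged rows")
        parts.append((l.locus_id, offset, offset + width))
        for t in taxa:
            chunks[t].append(l.rows.get(t, "?" * width))
        offset += width
    return Supermatrix(taxa, {t: "".join(chunks[t]) for t in taxa}, parts)


def write_supermatrix_fasta(sm: Supermatrix, path: str) -> None:
    with open(path, "w") as fh:
        for t in sm.taxa:
            fh.write(f">{t}\n{sm.rows[t]}\n")


def write_phylip(sm: Supermatrix, path: str) -> None:
    """Relaxed PHYLIP: full names, two-space separator."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_columns}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.rows[t]}\n")


def write_partitions(sm: Supermatrix, path: str) -> None:
    """RAxML-style partition file, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for locus_id, start, end in sm.partitions:
            fh.write(f"DNA, {locus_id} = {start + 1}-{end}\n")
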