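"""File I/O: FASTA, locus sidecar tables, truth tables, flat configs.

All tabular outputs are plain TSV; coordinates in sidecar files are 0-based
half-open alignment columns (stated in each header).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from retromark.markers import InsertionCall, LocusAlignment, MarkerRecord
from retromark.simulate import SimTruth

__all__ = [
    "read_fasta", "write_fasta",
    "write_locus_set", "read_locus_dir",
    "write_truth_table", "read_truth_table",
    "write_marker_records", "read_config",
]

SIDECAR_NAME = "spans.tsv"
TRUTH_NAME = "truth.tsv"


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence}; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_locus_set(loci: list[LocusAlignment], outdir: str | Path,
                    truths: list[SimTruth] | None = None) -> None:
    """Write per-locus FASTA files plus the span sidecar (and truth table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for locus in loci:
        write_fasta(locus.rows, outdir / f"{locus.locus_id}.fa")
        rows.append({
            "locus_id": locus.locus_id,
            "ref_taxon": locus.ref_taxon,
            "element_start": locus.element_span[0],
            "element_end": locus.element_span[1],
        })
    with open(outdir / SIDECAR_NAME, "w") as fh:
        fh.write("# coordinates: 0-based, half-open, alignment columns\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    if truths is not None:
        write_truth_table(truths, outdir / TRUTH_NAME)


def read_locus_dir(directory: str | Path) -> list[LocusAlignment]:
    """Read loci written by :func:`write_locus_set` (FASTA + spans sidecar)."""
    directory = Path(directory)
    sidecar = directory / SIDECAR_NAME
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    df = pd.read_csv(sidecar, sep="\t", comment="#")
    loci = []
    for row in df.itertuples():
        fa = directory / f"{row.locus_id}.fa"
        loci.append(LocusAlignment(
            locus_id=str(row.locus_id),
            rows=read_fasta(fa),
            element_span=(int(row.element_start), int(row.element_end)),
            ref_taxon=str(row.ref_taxon),
        ))
    return loci


def write_truth_table(truths: list[SimTruth], path: str | Path) -> None:
    taxa = sorted({t for tr in truths for t in tr.per_taxon_state})
    rows = []
    for tr in truths:
        row = {
            "locus_id": tr.locus_id,
            "insertion_branch": tr.insertion_branch,
            "tsd_sequence": tr.tsd_sequence,
            "is_ils": int(tr.is_ils),
        }
        row.update({t: tr.per_taxon_state.get(t, "?") for t in taxa})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[SimTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = {"locus_id", "insertion_branch", "tsd_sequence", "is_ils"}
    taxa = [c for c in df.columns if c not in meta]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        out.append(SimTruth(
            locus_id=d["locus_id"],
            insertion_branch=d["insertion_branch"],
            tsd_sequence=d["tsd_sequence"],
            per_taxon_state={t: d[t] for t in taxa},
            is_ils=bool(int(d["is_ils"])),
        ))
    return out


def write_marker_records(records: list[MarkerRecord], path: str | Path) -> None:
    """Flat per-call report: one row per (locus, taxon)."""
    rows = []
    for rec in records:
        for c in rec.calls:
            rows.append({
                "locus_id": rec.locus_id,
                "valid": int(rec.valid),
                "re_class": rec.re_class,
                "failure_reasons": ";".join(rec.failure_reasons),
                "taxon": c.taxon,
                "state": c.state,
                "left_junction": c.left_junction,
                "right_junction": c.right_junction,
                "tsd": c.tsd or "",
                "orientation": c.orientation or "",
                "subtype": c.subtype or "",
                "reasons": ";".join(c.reasons),
            })
    with open(path, "w") as fh:
        fh.write("# junctions: 0-based, half-open, alignment columns\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
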