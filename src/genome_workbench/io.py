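"""Readers and writers for the plain-text formats the workbench exchanges.

FASTA/FASTQ go through Biopython; `.pairs` and count tables through pandas.
All sequences are stored uppercase; FASTA is wrapped at 60 columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import AlignmentRecord, SequenceRecord

PAIRS_COLUMNS = ["readID", "chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Duplicate ids and non-IUPAC characters raise ValueError; an empty file
    yields an empty list.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality: int = 30) -> None:
    """Write (id, seq) pairs as FASTQ with a flat Phred+33 quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write Hi-C contacts in a minimal 7-column `.pairs`-like dialect."""
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: " + " ".join(PAIRS_COLUMNS) + "\n")
        pairs.to_csv(fh, sep="\t", header=False, index=False,
                     columns=PAIRS_COLUMNS)


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=PAIRS_COLUMNS)
    return df


def write_paf(alignments: Iterable[AlignmentRecord], path: str | Path,
              target_lengths: dict[str, int] | None = None) -> None:
    target_lengths = target_lengths or {}
    with open(path, "w") as fh:
        for a in alignments:
            tlen = target_lengths.get(a.target, a.target_end)
            fh.write("\t".join(map(str, [
                a.query, a.query_length, a.query_start, a.query_end,
                a.strand, a.target, tlen, a.target_start, a.target_end,
                a.matches, a.block_length, a.mapq,
            ])) + "\n")


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Parse a PAF file (12+ columns) into AlignmentRecords.

    Malformed lines raise ValueError naming the line number. Minus-strand
    records keep target-forward coordinates, as PAF does.
    """
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=12 PAF columns, got {len(fields)}"
                )
            try:
                qlen, qs, qe = int(fields[1]), int(fields[2]), int(fields[3])
                ts, te = int(fields[7]), int(fields[8])
                matches, block = int(fields[9]), int(fields[10])
                mapq = int(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            out.append(AlignmentRecord(
                query=fields[0], query_length=qlen, query_start=qs, query_end=qe,
                target=fields[5], target_start=ts, target_end=te,
                strand=fields[4], matches=matches, block_length=block, mapq=mapq,
                clip_left=qs, clip_right=qlen - qe,
            ))
    return out


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_bed(features: Sequence[tuple], path: str | Path) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for row in features:
            fh.write("\t".join(map(str, row)) + "\n")


def write_gff3(features: Sequence[dict], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive coordinates).

    Each feature dict needs: contig, source, type, start, end (0-based
    half-open, converted here), score, strand, attributes (dict).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f["attributes"].items())
            fh.write("\t".join(map(str, [
                f["contig"], f.get("source", "workbench"), f["type"],
                f["start"] + 1, f["end"], f.get("score", "."),
                f["strand"], ".", attrs,
            ])) + "\n")
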