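"""FASTA and BED readers/writers for genomes, transcripts and origins.

Transcripts are BED6 (chrom, start, end, name, score, strand); origins are
BED3 intervals whose midpoint is the origin position.  All BED coordinates
are 0-based, half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .asymmetry import Transcript


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_transcripts_bed(transcripts: list[Transcript], path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.chrom, t.start, t.end, t.id, 0, t.strand) for t in transcripts]
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_transcripts_bed(path: str | Path) -> list[Transcript]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return [
        Transcript(chrom=r.chrom, start=int(r.start), end=int(r.end),
                   strand=r.strand, id=r.name)
        for r in df.itertuples()
    ]


def write_origins_bed(origins: dict[str, list[int]], path: str | Path) -> None:
    rows = [(c, o, o + 1, f"origin_{c}_{i}")
            for c, olist in origins.items() for i, o in enumerate(olist)]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_origins_bed(path: str | Path) -> dict[str, list[int]]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    out: dict[str, list[int]] = {}
    for r in df.itertuples():
        out.setdefault(r.chrom, []).append((int(r.start) + int(r.end)) // 2)
    return {c: sorted(v) for c, v in out.items()}
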