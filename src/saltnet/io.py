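"""File-format boundaries: GTF, FASTA and the pipeline's TSV tables.

GTF is written 1-based closed with gene_id / transcript_id / biotype
attributes on exon features; reading goes through gffutils.  FASTA reading
uses pyfaidx.  Small RNAs are RNA-alphabet in memory and written as DNA
(U->T) at the FASTA boundary.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Sequence

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .models import TranscriptModel, to_dna


def write_fasta(path: str, sequences: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            seq = to_dna(sequences[name])
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    fa = Fasta(path, sequence_always_upper=True, rebuild=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


def write_gtf(path: str, transcripts: Sequence[TranscriptModel]) -> None:
    """Emit exon records, 1-based closed coordinates."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            for s, e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'biotype "{t.biotype}";'
                )
                fh.write(
                    f"{t.chrom}\tsaltnet\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str) -> List[TranscriptModel]:
    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: Dict[str, dict] = {}
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        rec = grouped.setdefault(
            tid,
            dict(
                gene_id=f.attributes["gene_id"][0],
                chrom=f.seqid,
                strand=f.strand,
                biotype=(f.attributes["biotype"][0] if "biotype" in f.attributes else "other"),
                exons=[],
            ),
        )
        rec["exons"].append((f.start - 1, f.end))
    out = [
        TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
            biotype=rec["biotype"],
        )
        for tid, rec in grouped.items()
    ]
    return sorted(out, key=lambda t: (t.chrom, t.start, t.transcript_id))


def write_counts(path: str, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_table(path: str, table: pd.DataFrame, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
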