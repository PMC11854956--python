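"""Shared domain types for the ceRNA-network pipeline.

Coordinates are 0-based half-open internally; GTF emission converts to the
1-based closed convention at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple


class SaltnetError(Exception):
    """Base class for pipeline errors."""


class SizingError(SaltnetError):
    """Requested synthetic features exceed chromosome capacity."""


class ConstructionError(SaltnetError):
    """A planted site could not be built to its intended label."""


class NormalizationError(SaltnetError):
    """Invalid normalisation denominator (zero library / mapped reads)."""


class InputError(SaltnetError):
    """Missing or malformed input record."""


Interval = Tuple[int, int]


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-structured transcript on a genome.

    exons are sorted, non-overlapping 0-based half-open intervals.
    biotype is one of mRNA, lncRNA_candidate, lncRNA, circRNA_host, other.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.transcript_id}: strand must be + or -")
        ex = tuple(sorted(tuple(e) for e in self.exons))
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if e1 > s2:
                raise InputError(f"{self.transcript_id}: overlapping exons")
        for s, e in ex:
            if e <= s:
                raise InputError(f"{self.transcript_id}: empty exon [{s},{e})")
        object.__setattr__(self, "exons", ex)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def five_prime(self) -> int:
        """0-based coordinate of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> Tuple[Interval, ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        )

    def extract(self, genome: str) -> str:
        """Spliced transcript sequence, 5'->3' (reverse-complemented on -)."""
        seq = "".join(genome[s:e] for s, e in self.exons)
        return revcomp_dna(seq) if self.strand == "-" else seq


_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def to_rna(seq: str) -> str:
    """DNA->RNA alphabet at the sequence boundary (T->U, uppercase)."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class CountMatrix:
    """Raw counts per feature per sample with group labels.

    counts is a pandas DataFrame (features x samples). groups maps each
    sample id to 'control' or 'treated'. library_sizes default to column
    sums when not supplied externally.
    """

    counts: "object"  # pandas.DataFrame
    groups: dict
    library_sizes: Optional[dict] = None

    def __post_init__(self) -> None:
        import numpy as np

        c = self.counts
        if (c.values < 0).any() or not np.isfinite(c.values).all():
            raise InputError("counts must be finite and non-negative")
        missing = [s for s in c.columns if s not in self.groups]
        if missing:
            raise InputError(f"samples without group label: {missing}")
        colsums = c.sum(axis=0)
        if self.library_sizes is None:
            self.library_sizes = {s: int(colsums[s]) for s in c.columns}
        else:
            for s in c.columns:
                if self.library_sizes.get(s, 0) < colsums[s]:
                    raise InputError(
                        f"library size for {s} below its column sum"
                    )

    def samples(self, group: str) -> list:
        return [s for s in self.counts.columns if self.groups[s] == group]
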