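"""Back-splice junction detection, circRNA typing and SRPBM quantification.

A back-splice joins a downstream donor to an upstream acceptor, so a
supporting chimeric read has its 3' segment mapped upstream of its 5'
segment.  A junction is accepted when it has at least one supporting read
with at most 2 mismatches and the donor-acceptor distance is under 100 kb;
rejected candidates are logged with the first failing rule in the
precedence mismatches > support > span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .models import TranscriptModel
from .quantify import srpbm

MAX_MISMATCHES = 2
MAX_SPAN = 100_000
BOUNDARY_TOLERANCE = 2


@dataclass
class BackspliceJunction:
    circ_id: str
    chrom: str
    acceptor: int  # upstream coordinate (0-based)
    donor: int  # downstream coordinate (0-based, exclusive end)
    strand: str
    junction_reads: int
    max_read_mismatches: int
    circ_type: str = "intergenic"
    n_exons: int = 1

    @property
    def span(self) -> int:
        return self.donor - self.acceptor


CHIMERIC_COLUMNS = [
    "read_id",
    "chrom",
    "seg1_start",
    "seg1_end",
    "seg2_start",
    "seg2_end",
    "strand",
    "mismatches",
]


def detect_backsplice(
    alignments: pd.DataFrame,
) -> Tuple[List[BackspliceJunction], pd.DataFrame]:
    """Group chimeric-segment records into junctions and apply the
    acceptance criteria.

    Each record carries two genomic segments of one read; a back-splice
    candidate requires the 3' segment (seg2) to map upstream of the 5'
    segment (seg1).  Returns (accepted junctions, rejection log with
    columns chrom, acceptor, donor, strand, reason).  Records whose
    segments are malformed are skipped and counted in the log attrs.
    """
    malformed = 0
    groups: Dict[Tuple[str, int, int, str], List[int]] = {}
    for _, rec in alignments.iterrows():
        try:
            s1s, s1e = int(rec["seg1_start"]), int(rec["seg1_end"])
            s2s, s2e = int(rec["seg2_start"]), int(rec["seg2_end"])
            chrom, strand = str(rec["chrom"]), str(rec["strand"])
            mm = int(rec["mismatches"])
        except (KeyError, ValueError, TypeError):
            malformed += 1
            continue
        if s1e <= s1s or s2e <= s2s or mm < 0:
            malformed += 1
            continue
        if s2s >= s1s:  # not back-spliced: 3' segment must lie upstream
            malformed += 1
            continue
        acceptor, donor = s2s, s1e
        groups.setdefault((chrom, acceptor, donor, strand), []).append(mm)

    accepted: List[BackspliceJunction] = []
    rejects = []
    for idx, key in enumerate(sorted(groups)):
        chrom, acceptor, donor, strand = key
        mms = groups[key]
        good = [m for m in mms if m <= MAX_MISMATCHES]
        span = donor - acceptor
        if mms and not good:
            reason = "mismatches"
        elif not good:
            reason = "support"
        elif span >= MAX_SPAN:
            reason = "span"
        else:
            accepted.append(
                BackspliceJunction(
                    circ_id=f"circ_{chrom}_{acceptor}_{donor}_{strand}",
                    chrom=chrom,
                    acceptor=acceptor,
                    donor=donor,
                    strand=strand,
                    junction_reads=len(good),
                    max_read_mismatches=max(good),
                )
            )
            continue
        rejects.append(
            dict(chrom=chrom, acceptor=acceptor, donor=donor, strand=strand,
                 reason=reason)
        )
    log = pd.DataFrame(
        rejects, columns=["chrom", "acceptor", "donor", "strand", "reason"]
    )
    log.attrs["malformed_records"] = malformed
    return accepted, log


def classify_circ(
    junction: BackspliceJunction,
    annotation: Sequence[TranscriptModel],
    tolerance: int = BOUNDARY_TOLERANCE,
) -> Tuple[str, int]:
    """Type a junction against the transcript annotation.

    exonic: acceptor and donor each coincide (within +-tolerance nt) with an
    exon start / exon end of one same-strand transcript; n_exons counts that
    transcript's exons enclosed by the junction interval (tolerance applied).
    ciRNA: the junction interval lies wholly within one same-strand intron.
    intergenic: everything else (including junctions overlapping annotation
    without matching boundaries).  Precedence exonic > ciRNA > intergenic.
    """
    a, d = junction.acceptor, junction.donor
    for t in annotation:
        if t.chrom != junction.chrom or t.strand != junction.strand:
            continue
        starts = [s for s, _ in t.exons]
        ends = [e for _, e in t.exons]
        if any(abs(a - s) <= tolerance for s in starts) and any(
            abs(d - e) <= tolerance for e in ends
        ):
            n = sum(
                1
                for s, e in t.exons
                if s >= a - tolerance and e <= d + tolerance
            )
            return "exonic", max(n, 1)
    for t in annotation:
        if t.chrom != junction.chrom or t.strand != junction.strand:
            continue
        if any(s <= a and d <= e for s, e in t.introns):
            return "ciRNA", 1
    return "intergenic", 1


def circ_sequence(
    junction: BackspliceJunction,
    annotation: Sequence[TranscriptModel],
    genome: str,
) -> str:
    """Back-splice-joined sequence of a circRNA (DNA alphabet, genome
    strand orientation for '+', reverse-complemented for '-').

    exonic circRNAs concatenate the enclosed exons of the matching
    transcript; ciRNA and intergenic circRNAs take the genomic interval.
    """
    from .models import revcomp_dna

    a, d = junction.acceptor, junction.donor
    circ_type, _ = classify_circ(junction, annotation)
    seq = None
    if circ_type == "exonic":
        for t in annotation:
            if t.chrom != junction.chrom or t.strand != junction.strand:
                continue
            starts = [s for s, _ in t.exons]
            ends = [e for _, e in t.exons]
            if any(abs(a - s) <= BOUNDARY_TOLERANCE for s in starts) and any(
                abs(d - e) <= BOUNDARY_TOLERANCE for e in ends
            ):
                seq = "".join(
                    genome[s:e]
                    for s, e in t.exons
                    if s >= a - BOUNDARY_TOLERANCE and e <= d + BOUNDARY_TOLERANCE
                )
                break
    if seq is None:
        seq = genome[a:d]
    return revcomp_dna(seq) if junction.strand == "-" else seq


def quantify_circ(
    junctions: Sequence[BackspliceJunction],
    junction_reads_per_sample: pd.DataFrame,
    mapped_reads: Dict[str, int],
) -> pd.DataFrame:
    """SRPBM per junction per sample.

    junction_reads_per_sample: circ_id x sample junction-read counts;
    junctions absent from a sample get 0.
    """
    rows = {}
    for j in junctions:
        vals = {}
        for sample, mapped in mapped_reads.items():
            reads = 0
            if (
                j.circ_id in junction_reads_per_sample.index
                and sample in junction_reads_per_sample.columns
            ):
                reads = int(junction_reads_per_sample.loc[j.circ_id, sample])
            vals[sample] = srpbm(reads, mapped) if reads else 0.0
        rows[j.circ_id] = vals
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "circ_id"
    return out
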