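"""lncRNA candidate filtering, positional classification and cis pairing.

Filtering retains assembled transcripts that (in rule order) show no
same-strand exonic overlap with a known mRNA, are at least 200 nt spliced,
have mean read coverage >= 3, CPC score < 0.5 and CNCI score < 0 — i.e. it
keeps the transcripts with low coding potential.

Retained lncRNAs are classified against the coding annotation with the
class codes i (intronic), j (bidirectional/divergent), o (sense exonic
overlap), u (intergenic) and x (antisense exonic overlap), resolved by the
precedence x > o > i > j > u.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import InputError, TranscriptModel

MIN_LENGTH = 200
MIN_COVERAGE = 3.0
MAX_CPC = 0.5
MAX_CNCI = 0.0
BIDIRECTIONAL_WINDOW = 1000
CIS_WINDOW = 100_000


@dataclass(frozen=True)
class CodingPotentialRecord:
    transcript_id: str
    cpc_score: float
    cnci_score: float
    coverage: float


def _exon_trees(
    transcripts: Iterable[TranscriptModel],
) -> Dict[Tuple[str, str], IntervalTree]:
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        tree = trees.setdefault((t.chrom, t.strand), IntervalTree())
        for s, e in t.exons:
            tree.addi(s, e, t.transcript_id)
    return trees


def filter_lncrna_candidates(
    candidates: Sequence[TranscriptModel],
    scores: Dict[str, CodingPotentialRecord],
    known_mrna: Sequence[TranscriptModel],
) -> Tuple[List[TranscriptModel], pd.DataFrame]:
    """Apply the lncRNA retention rules.

    Returns (retained transcripts, per-candidate table with `retained` and
    the first failing rule in `reason`).  Rule order: mrna_overlap, length,
    coverage, cpc, cnci.
    """
    mrna_exons = _exon_trees(known_mrna)
    rows = []
    retained = []
    for c in candidates:
        rec = scores.get(c.transcript_id)
        if rec is None:
            raise InputError(
                f"no coding-potential record for {c.transcript_id}"
            )
        tree = mrna_exons.get((c.chrom, c.strand))
        overlaps = bool(tree) and any(
            tree.overlap(s, e) for s, e in c.exons
        )
        if overlaps:
            reason = "mrna_overlap"
        elif c.spliced_length < MIN_LENGTH:
            reason = "length"
        elif rec.coverage < MIN_COVERAGE:
            reason = "coverage"
        elif not rec.cpc_score < MAX_CPC:
            reason = "cpc"
        elif not rec.cnci_score < MAX_CNCI:
            reason = "cnci"
        else:
            reason = "retained"
            retained.append(c)
        rows.append(dict(transcript_id=c.transcript_id, reason=reason))
    table = pd.DataFrame(rows, columns=["transcript_id", "reason"])
    table["retained"] = table["reason"] == "retained"
    return retained, table


def _spans_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if s1 < e2 and s2 < e1:
                return True
    return False


def _within_intron(lnc: TranscriptModel, coding: TranscriptModel) -> bool:
    return any(
        s <= lnc.start and lnc.end <= e for s, e in coding.introns
    )


def _divergent(lnc: TranscriptModel, coding: TranscriptModel, window: int) -> bool:
    """Head-to-head orientation with 5' ends within `window` nt.

    Opposite strands, 5' ends close, transcription pointing apart: the
    + strand member's 5' end must not lie 5'-ward of the - strand member's.
    """
    if lnc.strand == coding.strand:
        return False
    if abs(lnc.five_prime - coding.five_prime) > window:
        return False
    plus, minus = (lnc, coding) if lnc.strand == "+" else (coding, lnc)
    return plus.five_prime >= minus.five_prime


def classify_lncrna_position(
    lnc: TranscriptModel,
    coding: Sequence[TranscriptModel],
    intergenic_window: int = BIDIRECTIONAL_WINDOW,
) -> str:
    """Positional class code of a retained lncRNA: one of i, j, o, u, x.

    Precedence: x (antisense exonic overlap) > o (sense exonic overlap) >
    i (contained in a same-strand intron) > j (divergent 5' ends within the
    window, opposite strands, no overlap) > u (intergenic).
    """
    same_chrom = [c for c in coding if c.chrom == lnc.chrom]
    for c in same_chrom:
        if c.strand != lnc.strand and _exonic_overlap(lnc, c):
            return "x"
    for c in same_chrom:
        if c.strand == lnc.strand and _exonic_overlap(lnc, c):
            return "o"
    for c in same_chrom:
        if c.strand == lnc.strand and _within_intron(lnc, c):
            return "i"
    for c in same_chrom:
        if not _spans_overlap(lnc.span, c.span) and _divergent(
            lnc, c, intergenic_window
        ):
            return "j"
    return "u"


def span_distance(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Gap in nt between two genomic spans; 0 when they touch or overlap."""
    return max(a[0] - b[1], b[0] - a[1], 0)


def cis_targets(
    de_lnc: Sequence[TranscriptModel],
    genes: Sequence[TranscriptModel],
    expr: Optional[pd.DataFrame] = None,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Pair differential lncRNAs with genes within `window` nt (boundary
    inclusive; overlap counts as distance 0) and annotate the Pearson
    correlation of log2(expression + 1) across samples.

    expr: DataFrame of per-sample expression values (features x samples)
    covering both pair members; constant vectors give correlation NA.
    """
    rows = []
    for lnc in de_lnc:
        for g in genes:
            if g.chrom != lnc.chrom or g.transcript_id == lnc.transcript_id:
                continue
            d = span_distance(lnc.span, g.span)
            if d > window:
                continue
            corr = np.nan
            if expr is not None and lnc.transcript_id in expr.index and (
                g.transcript_id in expr.index
            ):
                x = np.log2(expr.loc[lnc.transcript_id].values.astype(float) + 1)
                y = np.log2(expr.loc[g.transcript_id].values.astype(float) + 1)
                if np.std(x) > 0 and np.std(y) > 0:
                    corr = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                dict(
                    lncrna_id=lnc.transcript_id,
                    gene_id=g.transcript_id,
                    distance=d,
                    correlation=corr,
                    sign=(
                        "NA"
                        if np.isnan(corr)
                        else ("positive" if corr > 0 else "negative")
                    ),
                )
            )
    return pd.DataFrame(
        rows, columns=["lncrna_id", "gene_id", "distance", "correlation", "sign"]
    )


_STOPS = {"UAA", "UAG", "UGA", "TAA", "TAG", "TGA"}


def longest_orf(sequence: str) -> int:
    """Length in nt of the longest ATG-initiated, in-frame stop-terminated
    ORF over the three forward frames (stop codon included); 0 if none.
    Ambiguity codes never match a start or stop."""
    seq = sequence.upper().replace("U", "T")
    best = 0
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best
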