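"""miRNA:target duplex alignment and scoring.

Implements the plant small-RNA target-scoring convention: a global gapped
alignment of the miRNA (5'->3') against the reverse complement of a candidate
site, scored by the additive Allen penalty (mismatch 1, G:U wobble 0.5, each
bulged nucleotide 1, all penalties doubled when the miRNA position involved
lies in positions 2-13 from the 5' end), plus a simplified nearest-neighbour
duplex energy used for the MFE ratio filter.

Internally Allen penalties are kept in half-units (integers) so the dynamic
program is exact; public scores are floats in conventional units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .models import InputError, revcomp_rna, to_rna


class State(str, Enum):
    """Per-column duplex states, miRNA 5'->3' order."""

    WC_pair = "WC_pair"
    GU_wobble = "GU_wobble"
    mismatch = "mismatch"
    bulge_mirna = "bulge_mirna"
    bulge_target = "bulge_target"


PAIR_STATES = (State.WC_pair, State.GU_wobble)

# 5'-proximal region where penalties are doubled (1-based miRNA positions).
CORE_START, CORE_END = 2, 13

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}

# Nearest-neighbour stack energies (kcal/mol) keyed by the miRNA-strand
# dinucleotide of two consecutive paired positions.  The table is symmetric
# under reverse complementation of the step; G:U pairs are looked up through
# the same miRNA nucleotide (wobble treated as its Watson-Crick analogue for
# stacking).  These constants are part of this package's documented energy
# model, not a reproduction of any external parameter set.
STACK_TABLE: Dict[str, float] = {
    "AA": -0.93, "AU": -1.10, "AC": -2.24, "AG": -2.08,
    "UA": -1.33, "UU": -0.93, "UC": -2.35, "UG": -2.11,
    "CA": -2.11, "CU": -2.08, "CC": -3.26, "CG": -2.36,
    "GA": -2.35, "GU": -2.24, "GC": -3.42, "GG": -3.26,
}
LOOP_PENALTY = 3.0  # kcal/mol per internal loop or bulge event
ENERGY_MODEL_VERSION = "saltnet-nn-1"


@dataclass
class DuplexAlignment:
    """A scored miRNA-vs-site pairing.

    site coordinates are relative to the target transcript (0-based
    half-open) when produced by a scan, else (0, len(site)).
    """

    mirna_id: str
    target_id: str
    site_start: int
    site_end: int
    mirna_seq: str
    site_seq: str
    states: Tuple[State, ...]
    allen_score: float
    mfe: float
    mfe_perfect: float
    mfe_ratio: float

    @property
    def n_bulges(self) -> int:
        return sum(
            1 for s in self.states if s in (State.bulge_mirna, State.bulge_target)
        )

    def pairing_string(self) -> str:
        """Compact one-char-per-column notation: | pair, o wobble, x mismatch,
        - miRNA bulge, ^ target bulge."""
        sym = {
            State.WC_pair: "|",
            State.GU_wobble: "o",
            State.mismatch: "x",
            State.bulge_mirna: "-",
            State.bulge_target: "^",
        }
        return "".join(sym[s] for s in self.states)


def _pair_kind(m: str, r: str) -> State:
    """State of miRNA nt `m` opposite reverse-complemented site nt `r`.

    Working on the reverse complement turns Watson-Crick pairing into
    character identity; the wobble pairs G:U and U:G become (G,A) and (U,C).
    """
    if m == r:
        return State.WC_pair
    if (m, r) in (("G", "A"), ("U", "C")):
        return State.GU_wobble
    return State.mismatch


def _in_core(pos: int) -> bool:
    return CORE_START <= pos <= CORE_END


def _column_halfcost(state: State, pos: int) -> int:
    """Allen penalty in half-units for a column at miRNA position `pos`.

    For a target bulge `pos` is the last miRNA position already consumed;
    the bulge is doubled when either flanking position (pos or pos+1) lies
    in the core.
    """
    if state is State.WC_pair:
        return 0
    if state is State.GU_wobble:
        base = 1
        double = _in_core(pos)
    elif state is State.mismatch:
        base = 2
        double = _in_core(pos)
    elif state is State.bulge_mirna:
        base = 2
        double = _in_core(pos)
    else:  # bulge_target, flanked by pos and pos+1
        base = 2
        double = _in_core(pos) or _in_core(pos + 1)
    return base * 2 if double else base


def allen_score(states: Sequence[State]) -> float:
    """Allen penalty of a state list (miRNA 5'->3'; bulge_target columns
    consume no miRNA position)."""
    pos = 0
    half = 0
    for s in states:
        if s is State.bulge_target:
            half += _column_halfcost(s, pos)
        else:
            pos += 1
            half += _column_halfcost(s, pos)
    return half / 2.0


def duplex_mfe(
    states: Sequence[State], mirna: str
) -> Tuple[float, float, float]:
    """Simplified nearest-neighbour duplex energy and MFE ratio.

    mfe sums stack energies over consecutive paired miRNA positions,
    plus LOOP_PENALTY per internal loop/bulge
    event (maximal unpaired run between two paired columns; terminal
    unpaired runs carry no penalty).  mfe_perfect is the same model on the
    fully Watson-Crick-paired miRNA.  Returns (mfe, mfe_perfect, ratio)
    with ratio clamped to [0, 1]; with zero paired positions mfe is 0 and
    the ratio 0.
    """
    mirna = to_rna(mirna)
    # map each paired column to its miRNA position (1-based)
    paired_pos: List[int] = []
    loop_events = 0
    pos = 0
    in_gap = False
    seen_pair = False
    pending_gap = False
    for s in states:
        consumes = s is not State.bulge_target
        if consumes:
            pos += 1
        if s in PAIR_STATES:
            if seen_pair and pending_gap:
                loop_events += 1
            pending_gap = False
            seen_pair = True
            paired_pos.append(pos)
        else:
            if seen_pair:
                pending_gap = True
    energy = 0.0
    for a, b in zip(paired_pos, paired_pos[1:]):
        if b == a + 1:
            energy += STACK_TABLE[mirna[a - 1] + mirna[b - 1]]
    energy += LOOP_PENALTY * loop_events
    perfect = sum(STACK_TABLE[mirna[i : i + 2]] for i in range(len(mirna) - 1))
    if not paired_pos:
        return 0.0, perfect, 0.0
    ratio = energy / perfect if perfect < 0 else 0.0
    ratio = min(1.0, max(0.0, ratio))
    return energy, perfect, ratio


def align_duplex(
    mirna: str,
    site: str,
    mirna_id: str = "mirna",
    target_id: str = "site",
    site_start: int = 0,
) -> DuplexAlignment:
    """Globally align a miRNA against a candidate site.

    Dynamic program over the miRNA (5'->3') and the reverse complement of
    the site, minimising the Allen score with ties broken toward fewer
    bulged nucleotides, then toward 5'-proximal pairing.  The site may not
    be shorter than the miRNA minus 3 nt.
    """
    m = to_rna(mirna)
    s = to_rna(site)
    if not (18 <= len(m) <= 25):
        raise InputError(f"{mirna_id}: miRNA length must be 18-25 nt")
    return _align_core(m, s, mirna_id, target_id, site_start)


def _align_core(
    m: str, s: str, mirna_id: str, target_id: str, site_start: int
) -> DuplexAlignment:
    M, T = len(m), len(s)
    if T < M - 3:
        raise InputError(
            f"site for {mirna_id} is unalignable: {T} nt < miRNA-3 ({M - 3})"
        )
    r = revcomp_rna(s)  # character identity == WC pairing
    INF = 1 << 30
    # D[i][j] = (halfcost, n_bulged_nts) best over alignments of m[:i] vs r[:j]
    D = [[(INF, INF)] * (T + 1) for _ in range(M + 1)]
    B = [[None] * (T + 1) for _ in range(M + 1)]  # backpointer move
    D[0][0] = (0, 0)
    for j in range(1, T + 1):
        c = _column_halfcost(State.bulge_target, 0)
        prev = D[0][j - 1]
        D[0][j] = (prev[0] + c, prev[1] + 1)
        B[0][j] = "t"
    for i in range(1, M + 1):
        c = _column_halfcost(State.bulge_mirna, i)
        prev = D[i - 1][0]
        D[i][0] = (prev[0] + c, prev[1] + 1)
        B[i][0] = "m"
        row, prow = D[i], D[i - 1]
        Bi = B[i]
        mi = m[i - 1]
        for j in range(1, T + 1):
            kind = _pair_kind(mi, r[j - 1])
            cd = _column_halfcost(kind, i)
            a = prow[j - 1]
            best = (a[0] + cd, a[1])
            move = "d"
            cm = _column_halfcost(State.bulge_mirna, i)
            a = prow[j]
            cand = (a[0] + cm, a[1] + 1)
            if cand < best:
                best, move = cand, "m"
            ct = _column_halfcost(State.bulge_target, i)
            a = row[j - 1]
            cand = (a[0] + ct, a[1] + 1)
            if cand < best:
                best, move = cand, "t"
            row[j] = best
            Bi[j] = move
    # traceback
    states: List[State] = []
    i, j = M, T
    while i > 0 or j > 0:
        mv = B[i][j]
        if mv == "d":
            states.append(_pair_kind(m[i - 1], r[j - 1]))
            i, j = i - 1, j - 1
        elif mv == "m":
            states.append(State.bulge_mirna)
            i -= 1
        else:
            states.append(State.bulge_target)
            j -= 1
    states.reverse()
    score = D[M][T][0] / 2.0
    mfe, perfect, ratio = duplex_mfe(states, m)
    return DuplexAlignment(
        mirna_id=mirna_id,
        target_id=target_id,
        site_start=site_start,
        site_end=site_start + T,
        mirna_seq=m,
        site_seq=s,
        states=tuple(states),
        allen_score=score,
        mfe=mfe,
        mfe_perfect=perfect,
        mfe_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# Fast window screening
# ---------------------------------------------------------------------------

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


def _batched_allen(
    m_arr: np.ndarray, windows: np.ndarray, free_site_ends: bool = False
) -> np.ndarray:
    """Exact minimal Allen half-score for each window (same recurrence as
    the scalar DP, vectorised across windows).  windows holds the reverse
    complement sense, shape (n, w).  With free_site_ends the window's
    terminal site overhangs cost nothing, so the result is the minimum over
    all global alignments of the miRNA to a contiguous sub-span."""
    M = len(m_arr)
    n, w = windows.shape
    # column cost per (miRNA pos i, window col j): depends on pair kind
    # pair kinds: identity -> WC (0); (G,A)=(2,0), (U,C)=(3,1) -> GU
    INF = np.int32(1 << 20)
    prev = np.empty((w + 1, n), dtype=np.int32)
    cur = np.empty_like(prev)
    bt0 = _column_halfcost(State.bulge_target, 0)
    prev[0] = 0
    for j in range(1, w + 1):
        prev[j] = 0 if free_site_ends else prev[j - 1] + bt0
    for i in range(1, M + 1):
        bm = _column_halfcost(State.bulge_mirna, i)
        bt = _column_halfcost(State.bulge_target, i)
        core = 2 if _in_core(i) else 1
        mi = m_arr[i - 1]
        col = windows  # (n, w)
        wc = col == mi
        gu = ((mi == 2) & (col == 0)) | ((mi == 3) & (col == 1))
        diag_cost = np.where(wc, 0, np.where(gu, core, 2 * core)).T  # (w, n)
        cur[0] = prev[0] + bm
        for j in range(1, w + 1):
            d = prev[j - 1] + diag_cost[j - 1]
            mgap = prev[j] + bm
            np.minimum(d, mgap, out=d)
            tgap = cur[j - 1] + bt
            np.minimum(d, tgap, out=d)
            cur[j] = d
        prev, cur = cur, prev
    if free_site_ends:
        return prev.min(axis=0)
    return prev[w].copy()


def scan_best_sites(
    mirna: str,
    transcript: str,
    max_halfscore: int,
    window_extra: int = 3,
    free_site_ends: bool = False,
) -> List[int]:
    """Return transcript start offsets of windows whose optimal Allen
    half-score is <= max_halfscore.  Window length is len(miRNA) +
    window_extra (or the whole transcript when shorter).  With
    free_site_ends a window's score is the best over all contiguous
    sub-spans (terminal site overhangs cost nothing)."""
    m = to_rna(mirna)
    t = to_rna(transcript)
    L = len(m)
    w = L + window_extra
    if len(t) < L - 3:
        return []
    if len(t) <= w:
        return [0]
    rc = _encode(revcomp_rna(t))
    win = np.lib.stride_tricks.sliding_window_view(rc, w)  # rc offset k
    scores = _batched_allen(_encode(m), win, free_site_ends=free_site_ends)
    # rc window k corresponds to transcript start len(t) - w - k
    hits = np.nonzero(scores <= max_halfscore)[0]
    return sorted(len(t) - w - int(k) for k in hits)


def predict_targets(
    mirnas: Dict[str, str],
    transcripts: Dict[str, str],
    allen_max: float = 7.0,
    mfe_ratio_min: float = 0.65,
    window_extra: int = 3,
    report_all_sites: bool = False,
) -> "pandas.DataFrame":
    """Scan every transcript window for each miRNA and report qualifying
    (miRNA, transcript) pairs.

    A pair is reported iff its best site satisfies allen_score <= allen_max
    and mfe_ratio > mfe_ratio_min; the best site has the lowest Allen score,
    ties broken by lower MFE then by 5'-most position.  Unpaired window
    overhangs are trimmed from reported sites (an embedded perfect
    complement scores 0), so candidate windows are rescanned over all site
    sub-spans of length >= miRNA-3.  Transcripts shorter than miRNA-3 are
    skipped.
    """
    import pandas as pd

    half_max = int(round(allen_max * 2))
    rows = []
    skipped = []
    for tid in sorted(transcripts):
        tseq = to_rna(transcripts[tid])
        for mid in sorted(mirnas):
            mseq = to_rna(mirnas[mid])
            L = len(mseq)
            if len(tseq) < L - 3:
                skipped.append((mid, tid))
                continue
            w = L + window_extra
            # free-end scan scores each window by its best contiguous
            # sub-span, so a window is a hit iff some trimmed site within
            # it meets the Allen threshold
            starts = scan_best_sites(
                mseq, tseq, half_max, window_extra, free_site_ends=True
            )
            seen = set()
            cands = []
            for st in starts:
                wl = min(w, len(tseq) - st)
                max_trim = wl - (L - 3)
                for i in range(max_trim + 1):
                    for j in range(max_trim - i + 1):
                        span = (st + i, st + wl - j)
                        if span in seen:
                            continue
                        seen.add(span)
                        cands.append(
                            align_duplex(
                                mseq, tseq[span[0] : span[1]], mid, tid,
                                site_start=span[0],
                            )
                        )
            cands.sort(key=lambda a: (a.allen_score, a.mfe, a.site_start))
            if not report_all_sites:
                cands = cands[:1]
            keep = [
                a
                for a in cands
                if a.allen_score <= allen_max and a.mfe_ratio > mfe_ratio_min
            ]
            for aln in keep:
                rows.append(
                    dict(
                        mirna_id=mid,
                        target_id=tid,
                        site_start=aln.site_start,
                        site_end=aln.site_end,
                        allen_score=aln.allen_score,
                        mfe=round(aln.mfe, 4),
                        mfe_ratio=round(aln.mfe_ratio, 6),
                        pairing=aln.pairing_string(),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "target_id",
            "site_start",
            "site_end",
            "allen_score",
            "mfe",
            "mfe_ratio",
            "pairing",
        ],
    )
    df.attrs["skipped"] = skipped
    return df.sort_values(["mirna_id", "target_id", "site_start"]).reset_index(
        drop=True
    )
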