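"""Endogenous target mimic (eTM / miRNA sponge) detection.

A lncRNA or circRNA site mimics a miRNA target when the duplex carries a
single short bulge on the ncRNA side opposite the centre of the miRNA
(blocking cleavage while preserving binding), with near-complete pairing
elsewhere: no mismatch at the central positions, at most four mismatches
outside them and no run of three or more consecutive mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .duplex import (
    DuplexAlignment,
    State,
    _encode,
    align_duplex,
)
from .models import revcomp_rna, to_rna

DEFAULT_MIDDLE: FrozenSet[int] = frozenset({9, 10, 11, 12})
MIN_BULGE, MAX_BULGE = 1, 5
MAX_MISMATCH_OUTSIDE = 4
MAX_CONSECUTIVE_MISMATCH = 2


@dataclass
class MimicCall:
    mirna_id: str
    ncrna_id: str
    site_start: int
    site_end: int
    bulge_position: Optional[int]  # ncRNA gap sits between miRNA pos and pos+1
    bulge_length: int
    n_mismatches_outside_middle: int
    max_consecutive_mismatches: int
    verdict: str  # pass | fail
    fail_reason: str  # bulge_side | bulge_position | middle_mismatch |
    #                   mismatch_count | consecutive_mismatches | none


def _bulge_events(states: Sequence[State]) -> List[Tuple[str, int, int]]:
    """Maximal bulge runs as (side, length, miRNA position before the run).

    side is 'mirna' or 'target'; for a target bulge the run sits between
    miRNA positions pos and pos+1.  For a miRNA bulge pos is the first
    bulged miRNA position.
    """
    events = []
    pos = 0
    i = 0
    n = len(states)
    while i < n:
        s = states[i]
        if s is State.bulge_target:
            j = i
            while j < n and states[j] is State.bulge_target:
                j += 1
            events.append(("target", j - i, pos))
            i = j
        elif s is State.bulge_mirna:
            j = i
            run_start_pos = pos + 1
            while j < n and states[j] is State.bulge_mirna:
                pos += 1
                j += 1
            events.append(("mirna", j - i, run_start_pos))
            i = j
        else:
            pos += 1
            i += 1
    return events


def etm_check(
    alignment: DuplexAlignment,
    middle: FrozenSet[int] = DEFAULT_MIDDLE,
) -> MimicCall:
    """Apply the three target-mimic rules to an aligned duplex.

    Rules, checked in order with the first violation recorded:
      1. exactly one bulge, on the ncRNA side, of 1-5 nt, lying between two
         miRNA positions that are both in the middle set;
      2. no mismatch at any middle position;
      3. at most four mismatches outside the middle and no run of three or
         more consecutive mismatches (bulges do not interrupt a run).
    """
    states = alignment.states
    # per-miRNA-position mismatch flags (bulges excluded, do not break runs)
    mm_flags: List[bool] = []
    mm_positions: List[int] = []
    pos = 0
    for s in states:
        if s is State.bulge_target:
            continue
        pos += 1
        if s is State.bulge_mirna:
            continue
        mm_flags.append(s is State.mismatch)
        if s is State.mismatch:
            mm_positions.append(pos)
    n_outside = sum(1 for p in mm_positions if p not in middle)
    max_run = run = 0
    for f in mm_flags:
        run = run + 1 if f else 0
        max_run = max(max_run, run)

    events = _bulge_events(states)
    tgt = [e for e in events if e[0] == "target"]
    bulge_pos = tgt[0][2] if len(tgt) == 1 else None
    bulge_len = tgt[0][1] if len(tgt) == 1 else sum(e[1] for e in tgt)

    reason = "none"
    if not events or any(e[0] == "mirna" for e in events):
        reason = "bulge_side"
    elif (
        len(tgt) != 1
        or not (MIN_BULGE <= tgt[0][1] <= MAX_BULGE)
        or tgt[0][2] not in middle
        or (tgt[0][2] + 1) not in middle
    ):
        reason = "bulge_position"
    elif any(p in middle for p in mm_positions):
        reason = "middle_mismatch"
    elif n_outside > MAX_MISMATCH_OUTSIDE:
        reason = "mismatch_count"
    elif max_run > MAX_CONSECUTIVE_MISMATCH:
        reason = "consecutive_mismatches"

    return MimicCall(
        mirna_id=alignment.mirna_id,
        ncrna_id=alignment.target_id,
        site_start=alignment.site_start,
        site_end=alignment.site_end,
        bulge_position=bulge_pos,
        bulge_length=bulge_len,
        n_mismatches_outside_middle=n_outside,
        max_consecutive_mismatches=max_run,
        verdict="pass" if reason == "none" else "fail",
        fail_reason=reason,
    )


def _screen_windows(
    m: str, t: str, middle: FrozenSet[int]
) -> List[Tuple[int, int]]:
    """Candidate (start, window_length) mimic sites in transcript t.

    Any alignment that can pass etm_check consists of two ungapped paired
    blocks around one ncRNA bulge of b nt (window length = miRNA + b), the
    gap between middle positions k/k+1, with bounded mismatches; this
    enumerates exactly those shapes with vectorised mismatch counting
    (G:U counts as paired), so it is a superset of all possible passes.
    """
    L = len(m)
    rc = _encode(revcomp_rna(t))
    m_arr = _encode(m)
    # mismatch matrix helper in rc space: pos i (1-based) vs rc char
    wob_a = m_arr == 2  # G pairs rc A
    wob_c = m_arr == 3  # U pairs rc C
    ks = sorted(k for k in middle if (k + 1) in middle)
    middle_idx = np.array(sorted(middle)) - 1
    out: List[Tuple[int, int]] = []
    for b in range(MIN_BULGE, MAX_BULGE + 1):
        w = L + b
        if len(t) < w:
            continue
        win = np.lib.stride_tricks.sliding_window_view(rc, w)  # (n, w)
        n = win.shape[0]
        for k in ks:
            # miRNA pos p (1-based) pairs rc col p-1 for p<=k, col p-1+b after
            cols = np.concatenate(
                [np.arange(k), np.arange(k, L) + b]
            )
            sub = win[:, cols]  # (n, L)
            mm = (sub != m_arr) & ~(
                (wob_a & (sub == 0)) | (wob_c & (sub == 1))
            )
            ok = ~mm[:, middle_idx].any(axis=1)
            ok &= (mm.sum(axis=1) - mm[:, middle_idx].sum(axis=1)) <= (
                MAX_MISMATCH_OUTSIDE
            )
            if L >= 3:
                run3 = (mm[:, :-2] & mm[:, 1:-1] & mm[:, 2:]).any(axis=1)
                ok &= ~run3
            for idx in np.nonzero(ok)[0]:
                out.append((len(t) - w - int(idx), w))
    return sorted(set(out))


def scan_mimics(
    mirnas: Dict[str, str],
    ncrnas: Dict[str, str],
    middle: FrozenSet[int] = DEFAULT_MIDDLE,
) -> "pandas.DataFrame":
    """All (miRNA, ncRNA) mimic sites that pass etm_check.

    circRNA sequences should be supplied in back-splice-joined form so
    junction-crossing sites are visible.  Output rows are passes only,
    ordered by (mirna_id, ncrna_id, site_start); overlapping passing windows
    for one pair are collapsed to the lowest-Allen (then 5'-most) site.
    """
    import pandas as pd

    rows = []
    for nid in sorted(ncrnas):
        t = to_rna(ncrnas[nid])
        for mid in sorted(mirnas):
            m = to_rna(mirnas[mid])
            if len(t) < len(m):
                continue
            passes = []
            for start, w in _screen_windows(m, t, middle):
                aln = align_duplex(m, t[start : start + w], mid, nid, site_start=start)
                call = etm_check(aln, middle)
                if call.verdict == "pass":
                    passes.append((aln, call))
            # collapse overlapping windows
            passes.sort(key=lambda ac: (ac[0].allen_score, ac[0].site_start))
            chosen: List[Tuple[DuplexAlignment, MimicCall]] = []
            for aln, call in passes:
                if any(
                    not (aln.site_end <= a.site_start or aln.site_start >= a.site_end)
                    for a, _ in chosen
                ):
                    continue
                chosen.append((aln, call))
            for aln, call in chosen:
                rows.append(
                    dict(
                        mirna_id=mid,
                        ncrna_id=nid,
                        site_start=call.site_start,
                        site_end=call.site_end,
                        bulge_position=call.bulge_position,
                        bulge_length=call.bulge_length,
                        n_mismatches_outside_middle=call.n_mismatches_outside_middle,
                        max_consecutive_mismatches=call.max_consecutive_mismatches,
                        allen_score=aln.allen_score,
                        verdict=call.verdict,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "ncrna_id",
            "site_start",
            "site_end",
            "bulge_position",
            "bulge_length",
            "n_mismatches_outside_middle",
            "max_consecutive_mismatches",
            "allen_score",
            "verdict",
        ],
    )
    return df.sort_values(["mirna_id", "ncrna_id", "site_start"]).reset_index(
        drop=True
    )
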