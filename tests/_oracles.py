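"""Independent reference implementations used only by the tests.

Everything here is written from the documented scoring/typing rules without
reusing the package's internals, so agreement between the two is evidence of
correctness rather than self-confirmation.
"""

from functools import lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# Allen cost model (half-units), reimplemented from the documented rules
# ---------------------------------------------------------------------------

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "U"), ("U", "G")}
CORE = set(range(2, 14))  # 1-based miRNA positions with doubled penalties

STACKS = {
    "AA": -0.93, "AU": -1.10, "AC": -2.24, "AG": -2.08,
    "UA": -1.33, "UU": -0.93, "UC": -2.35, "UG": -2.11,
    "CA": -2.11, "CU": -2.08, "CC": -3.26, "CG": -2.36,
    "GA": -2.35, "GU": -2.24, "GC": -3.42, "GG": -3.26,
}
LOOP = 3.0

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def pair_cost_half(m_nt, s_nt, pos):
    """Half-unit Allen cost of pairing miRNA nt (1-based pos) with site nt."""
    if (m_nt, s_nt) in WC:
        base = 0
    elif (m_nt, s_nt) in GU:
        base = 1
    else:
        base = 2
    return base * 2 if base and pos in CORE else base


def mirna_bulge_half(pos):
    return 4 if pos in CORE else 2


def site_bulge_half(pos):
    """pos = last miRNA position consumed before the bulged site nt."""
    return 4 if (pos in CORE or (pos + 1) in CORE) else 2


def oracle_best(mirna, site):
    """Minimal (half-cost, bulged-nt count) over all global alignments of
    the miRNA against the site, by memoised recursion over suffixes.

    The site is consumed 3'->5' so that site index j pairs miRNA position i
    the way the reverse-complement alignment does.
    """
    M, T = len(mirna), len(site)
    rc = revcomp(site)  # rc[j] complements site base pairing m position

    @lru_cache(maxsize=None)
    def go(i, j):
        if i == 0 and j == 0:
            return (0, 0)
        best = (1 << 30, 1 << 30)
        if i > 0 and j > 0:
            # pairing m[i-1] against the site base whose complement is rc[j-1]
            c = pair_cost_half(mirna[i - 1], _COMP[rc[j - 1]], i)
            h, b = go(i - 1, j - 1)
            best = min(best, (h + c, b))
        if i > 0:
            h, b = go(i - 1, j)
            best = min(best, (h + mirna_bulge_half(i), b + 1))
        if j > 0:
            h, b = go(i, j - 1)
            best = min(best, (h + site_bulge_half(i), b + 1))
        return best

    out = go(M, T)
    go.cache_clear()
    return out


def oracle_enumerate(mirna, site):
    """Exhaustive enumeration of every global alignment (no memoisation).

    Returns (best_halfcost, best_bulged, mfe_values) where mfe_values is the
    set of duplex energies of all alignments attaining the minimum
    (halfcost, bulged) pair.
    """
    M, T = len(mirna), len(site)
    rc = revcomp(site)
    results = []

    def walk(i, j, states):
        if i == M and j == T:
            results.append(tuple(states))
            return
        if i < M and j < T:
            m_nt, s_nt = mirna[i], _COMP[rc[j]]
            if (m_nt, s_nt) in WC:
                k = "p"
            elif (m_nt, s_nt) in GU:
                k = "g"
            else:
                k = "x"
            states.append(k)
            walk(i + 1, j + 1, states)
            states.pop()
        if i < M:
            states.append("m")  # miRNA bulge
            walk(i + 1, j, states)
            states.pop()
        if j < T:
            states.append("t")  # site bulge
            walk(i, j + 1, states)
            states.pop()

    walk(0, 0, [])
    best = (1 << 30, 1 << 30)
    best_mfes = set()
    for states in results:
        half = 0
        bulged = 0
        pos = 0
        for s in states:
            if s == "t":
                half += site_bulge_half(pos)
                bulged += 1
                continue
            pos += 1
            if s == "m":
                half += mirna_bulge_half(pos)
                bulged += 1
            elif s == "g":
                half += 2 if pos in CORE else 1
            elif s == "x":
                half += 4 if pos in CORE else 2
        key = (half, bulged)
        if key < best:
            best = key
            best_mfes = {oracle_mfe_states(states, mirna)}
        elif key == best:
            best_mfes.add(oracle_mfe_states(states, mirna))
    return best[0], best[1], best_mfes


def oracle_mfe_states(states, mirna):
    """Stack-walk duplex energy of a compact state string list.

    states use p/g (paired), x (mismatch), m (miRNA bulge), t (site bulge).
    """
    paired = []
    pos = 0
    for s in states:
        if s != "t":
            pos += 1
        if s in ("p", "g"):
            paired.append(pos)
    if not paired:
        return 0.0
    energy = 0.0
    for a, b in zip(paired, paired[1:]):
        if b == a + 1:
            energy += STACKS[mirna[a - 1] + mirna[b - 1]]
    # loop events: maximal non-paired column runs strictly between pairs
    symbols = ["P" if s in ("p", "g") else "." for s in states]
    trimmed = "".join(symbols).strip(".")
    loops = sum(1 for chunk in trimmed.split("P") if chunk)
    return energy + LOOP * loops


def oracle_mfe_alignment(aln):
    """Stack-walk energy of a package DuplexAlignment, via its state names."""
    code = {
        "WC_pair": "p",
        "GU_wobble": "g",
        "mismatch": "x",
        "bulge_mirna": "m",
        "bulge_target": "t",
    }
    return oracle_mfe_states([code[s.value] for s in aln.states], aln.mirna_seq)


# ---------------------------------------------------------------------------
# Interval-logic brute force
# ---------------------------------------------------------------------------


def _exon_bases(t):
    out = set()
    for s, e in t.exons:
        out.update(range(s, e))
    return out


def _intron_intervals(t):
    return [
        (e1, s2)
        for (_, e1), (s2, _) in zip(t.exons, t.exons[1:])
        if s2 > e1
    ]


def brute_lncrna_class(lnc, coding, window=1000):
    """Per-base reimplementation of the positional class codes."""
    same = [c for c in coding if c.chrom == lnc.chrom]
    lnc_ex = _exon_bases(lnc)
    for c in same:
        if c.strand != lnc.strand and lnc_ex & _exon_bases(c):
            return "x"
    for c in same:
        if c.strand == lnc.strand and lnc_ex & _exon_bases(c):
            return "o"
    span = set(range(lnc.start, lnc.end))
    for c in same:
        if c.strand != lnc.strand:
            continue
        for s, e in _intron_intervals(c):
            if span <= set(range(s, e)):
                return "i"
    for c in same:
        if c.strand == lnc.strand:
            continue
        if span & set(range(c.start, c.end)):
            continue
        lnc5 = lnc.start if lnc.strand == "+" else lnc.end - 1
        c5 = c.start if c.strand == "+" else c.end - 1
        if abs(lnc5 - c5) > window:
            continue
        plus5, minus5 = (lnc5, c5) if lnc.strand == "+" else (c5, lnc5)
        if plus5 >= minus5:
            return "j"
    return "u"


def brute_circ_type(chrom, acceptor, donor, strand, annotation, tol=2):
    """Per-base reimplementation of circRNA typing."""
    for t in annotation:
        if t.chrom != chrom or t.strand != strand:
            continue
        starts = {s for s, _ in t.exons}
        ends = {e for _, e in t.exons}
        if any(abs(acceptor - s) <= tol for s in starts) and any(
            abs(donor - e) <= tol for e in ends
        ):
            n = sum(
                1
                for s, e in t.exons
                if s >= acceptor - tol and e <= donor + tol
            )
            return "exonic", max(n, 1)
    span = set(range(acceptor, donor))
    for t in annotation:
        if t.chrom != chrom or t.strand != strand:
            continue
        for s, e in _intron_intervals(t):
            if span <= set(range(s, e)):
                return "ciRNA", 1
    return "intergenic", 1


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def naive_bh(pvals):
    """Quadratic-time Benjamini-Hochberg step-up reference."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj[i] = running_min
    return np.minimum(adj, 1.0)
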