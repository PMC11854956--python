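"""Synthetic fixtures with known ground truth for every pipeline stage.

The generator emulates the study design this pipeline targets: a single
plant chromosome carrying multi-exon mRNAs (mostly > 1 kb) and short
1-2-exon lncRNA candidates (mostly < 600 nt); 18-25 nt miRNAs; two
conditions (control vs salt-treated) with three biological replicates of
negative-binomial counts (variance = mu + phi*mu^2) and planted log2 fold
changes; miRNA target and target-mimic sites written into the genome so
they survive a round trip through annotation and sequence extraction; and
back-splice junction reads exercising every circRNA acceptance rule.

Decoy constructions violate exactly one downstream rule each, so test
failures are attributable to a single rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import circrna as circ_mod
from . import duplex as duplex_mod
from . import mimic as mimic_mod
from .models import (
    ConstructionError,
    CountMatrix,
    InputError,
    SizingError,
    TranscriptModel,
    revcomp_rna,
    to_rna,
)

_NTS = np.array(list("ACGT"))
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic dataset."""

    seed: int = 42
    n_genes: int = 60
    n_lncrna: int = 40
    n_mirna: int = 10
    n_circ: int = 20
    n_samples_per_group: int = 3
    dispersion: float = 0.1
    de_fraction: float = 0.3
    planted_log2fc: float = 2.0
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    planted_targets: list = field(default_factory=list)
    planted_mimics: list = field(default_factory=list)
    planted_junctions: list = field(default_factory=list)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.seed + 1_000_003 * salt)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------


def make_annotation(
    scenario: SyntheticScenario,
) -> Tuple[List[TranscriptModel], str]:
    """Random genome plus mRNA and lncRNA-candidate transcript models.

    Features are placed left to right with random gaps; raises SizingError
    when the requested features do not fit on the chromosome.
    """
    if scenario.n_genes < 0 or scenario.n_lncrna < 0:
        raise InputError("feature counts must be non-negative")
    rng = scenario.rng(1)
    genome = "".join(rng.choice(_NTS, size=scenario.chrom_length))

    transcripts: List[TranscriptModel] = []
    cursor = 2000
    order = ["mRNA"] * scenario.n_genes + ["lncRNA_candidate"] * scenario.n_lncrna
    rng.shuffle(order)
    n_m = n_l = 0
    for kind in order:
        cursor += int(rng.integers(500, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        if kind == "mRNA":
            n_m += 1
            tid, gid = f"mRNA{n_m:04d}", f"gene{n_m:04d}"
            n_ex = int(rng.integers(2, 10))
            for _ in range(n_ex):
                elen = int(rng.integers(150, 450))
                exons.append((pos, pos + elen))
                pos += elen + int(rng.integers(80, 900))
        else:
            n_l += 1
            tid = gid = f"lnc{n_l:04d}"
            total = int(np.clip(rng.lognormal(np.log(380), 0.45), 120, 1500))
            n_ex = 1 if rng.random() < 0.6 or total < 240 else 2
            if n_ex == 1:
                exons.append((pos, pos + total))
                pos += total
            else:
                l1 = total // 2
                exons.append((pos, pos + l1))
                pos += l1 + int(rng.integers(80, 500))
                exons.append((pos, pos + total - l1))
                pos += total - l1
        if pos >= scenario.chrom_length - 2000:
            raise SizingError(
                f"features exceed chromosome capacity at {pos} nt; "
                f"increase chrom_length"
            )
        cursor = pos
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=scenario.chrom,
                strand=strand,
                exons=tuple(exons),
                biotype=kind,
            )
        )
    return transcripts, genome


def _wobble_capacity(seq: str) -> float:
    """Total Allen penalty reachable with G:U wobbles alone (core wobbles
    cost 1, others 0.5)."""
    return sum(
        (1.0 if 2 <= pos <= 13 else 0.5)
        for pos, c in enumerate(seq, start=1)
        if c in "GU"
    )


def make_mirnas(scenario: SyntheticScenario) -> Dict[str, str]:
    """Random 18-25 nt miRNAs (RNA alphabet) with enough G/U content that a
    wobble-only decoy exceeding the Allen threshold is constructible."""
    rng = scenario.rng(2)
    out: Dict[str, str] = {}
    for i in range(scenario.n_mirna):
        while True:
            L = int(rng.integers(18, 26))
            seq = "".join(rng.choice(np.array(list("ACGU")), size=L))
            if _wobble_capacity(seq) > 7.5:
                break
        out[f"miR{i + 1:03d}"] = seq
    return out


# ---------------------------------------------------------------------------
# Sequence planting
# ---------------------------------------------------------------------------


def _genome_posmap(t: TranscriptModel) -> List[int]:
    """Genome coordinate of each spliced-transcript position (5'->3')."""
    concat = [p for s, e in t.exons for p in range(s, e)]
    return concat[::-1] if t.strand == "-" else concat


def _write_site(
    genome: bytearray, t: TranscriptModel, t_start: int, site_rna: str
) -> None:
    """Write `site_rna` (transcript orientation) into the genome so the
    extracted spliced sequence contains it at t_start."""
    posmap = _genome_posmap(t)
    site_dna = site_rna.replace("U", "T")
    for k, ch in enumerate(site_dna):
        gpos = posmap[t_start + k]
        if t.strand == "-":
            ch = {"A": "T", "C": "G", "G": "C", "T": "A"}[ch]
        genome[gpos] = ord(ch)


def _site_index(L: int, pos: int) -> int:
    """0-based site index pairing miRNA position `pos` (1-based), for a
    site that is the reverse complement of the miRNA."""
    return L - pos


def _perfect_site(mirna: str) -> str:
    return revcomp_rna(mirna)


def _apply_wobble(site: List[str], mirna: str, pos: int) -> bool:
    """Turn the pair at miRNA position pos into a G:U wobble; returns
    False when the miRNA nucleotide cannot wobble."""
    i = _site_index(len(mirna), pos)
    m = mirna[pos - 1]
    if m == "G":
        site[i] = "U"
    elif m == "U":
        site[i] = "G"
    else:
        return False
    return True


# site nucleotides that neither Watson-Crick- nor wobble-pair the miRNA nt
_MISMATCH_SITE_NTS = {"A": "ACG", "C": "ACU", "G": "AG", "U": "CU"}


def _apply_mismatch(
    site: List[str], mirna: str, pos: int, rng: Optional[np.random.Generator] = None
) -> None:
    choices = _MISMATCH_SITE_NTS[mirna[pos - 1]]
    nt = choices[0] if rng is None else choices[int(rng.integers(len(choices)))]
    site[_site_index(len(mirna), pos)] = nt


def _target_site(
    mirna: str,
    decoy_rule: Optional[str],
    rng: Optional[np.random.Generator] = None,
) -> str:
    """A target site sequence: perfect complement, or a decoy violating
    exactly one predict_targets rule (allen or mfe_ratio)."""
    L = len(mirna)
    site = list(_perfect_site(mirna))
    if decoy_rule is None:
        pass
    elif decoy_rule == "allen":
        # wobbles keep the duplex paired (MFE ratio stays 1) while adding
        # Allen penalty; core positions first (1.0 each, then 0.5)
        order = sorted(range(1, L + 1), key=lambda p: not 2 <= p <= 13)
        if rng is not None:
            order = list(rng.permutation(order))
        added = 0.0
        for pos in order:
            if added > 7.0:
                break
            if _apply_wobble(site, mirna, int(pos)):
                added += 1.0 if 2 <= pos <= 13 else 0.5
        if added <= 7.0:
            raise ConstructionError("miRNA lacks wobble capacity for an Allen decoy")
    elif decoy_rule == "mfe_ratio":
        # three spread core mismatches: Allen 6 (<=7) but the broken stacks
        # and loop penalties push the MFE ratio below 0.65
        for pos in (4, 7, 10):
            _apply_mismatch(site, mirna, pos, rng)
    else:
        raise InputError(f"unknown target decoy rule: {decoy_rule}")
    return "".join(site)


def _mimic_site(
    mirna: str,
    rng: np.random.Generator,
    bulge_len: int,
    decoy_rule: Optional[str],
) -> str:
    """A target-mimic site: reverse complement with a central ncRNA-side
    insertion, or a decoy violating exactly one eTM rule."""
    L = len(mirna)
    site = list(_perfect_site(mirna))
    gap_after = 10  # bulge between miRNA positions 10 and 11 (middle)
    if decoy_rule == "bulge_side":
        # deletion opposite position 10 -> bulge on the miRNA side
        del site[_site_index(L, 10)]
        return "".join(site)
    if decoy_rule == "bulge_position":
        gap_after = 3
    if decoy_rule == "middle_mismatch":
        _apply_mismatch(site, mirna, int(rng.choice([9, 12])), rng)
    elif decoy_rule == "mismatch_count":
        head = int(rng.choice([2, 3]))
        for pos in (head, head + 2, head + 4, max(13, L - 5), L - 2):
            _apply_mismatch(site, mirna, int(pos), rng)
    elif decoy_rule == "consecutive_mismatches":
        start = int(rng.integers(13, L - 4))
        for pos in (start, start + 1, start + 2):
            _apply_mismatch(site, mirna, pos, rng)
    elif decoy_rule not in (None, "bulge_side", "bulge_position"):
        raise InputError(f"unknown mimic decoy rule: {decoy_rule}")
    if not 1 <= bulge_len <= 5:
        raise InputError("bulge_length must be in 1..5")
    # random insertion nucleotides; the caller verifies the construction
    # through the duplex aligner and retries on failure
    ins = "".join(rng.choice(np.array(list("ACGU")), size=bulge_len))
    cut = _site_index(L, gap_after)
    return "".join(site[:cut]) + ins + "".join(site[cut:])


def plant_duplex_sites(
    scenario: SyntheticScenario,
    transcripts: Sequence[TranscriptModel],
    genome: str,
    mirnas: Dict[str, str],
    mode: str,
    n_positive: int = 10,
    n_decoy: int = 10,
) -> Tuple[str, pd.DataFrame]:
    """Write target or mimic sites (plus single-rule decoys) into the
    genome, one site per host transcript, and return the edited genome with
    a ground-truth table.

    mode='target' hosts sites on mRNAs; mode='mimic' on lncRNA candidates.
    Each planted construction is verified through the duplex/mimic modules
    at build time; an unbuildable request raises ConstructionError.
    """
    if mode not in ("target", "mimic"):
        raise InputError("mode must be 'target' or 'mimic'")
    rng = scenario.rng(3 if mode == "target" else 4)
    host_type = "mRNA" if mode == "target" else "lncRNA_candidate"
    hosts = [t for t in transcripts if t.biotype == host_type]
    needed = n_positive + n_decoy
    max_len = max(len(s) for s in mirnas.values()) + 8
    hosts = [h for h in hosts if h.spliced_length >= max_len + 10]
    if len(hosts) < needed:
        raise SizingError(
            f"need {needed} host transcripts of >= {max_len + 10} nt, "
            f"have {len(hosts)}"
        )
    decoy_rules = (
        ["allen", "mfe_ratio"]
        if mode == "target"
        else [
            "bulge_side",
            "bulge_position",
            "middle_mismatch",
            "mismatch_count",
            "consecutive_mismatches",
        ]
    )
    gbuf = bytearray(genome.encode())
    mir_ids = sorted(mirnas)
    rows = []
    for k in range(needed):
        host = hosts[k]
        mid = mir_ids[k % len(mir_ids)]
        mseq = mirnas[mid]
        rule = None if k < n_positive else decoy_rules[(k - n_positive) % len(decoy_rules)]
        if mode == "target":
            # the aligner may discover a cheaper geometry for an unlucky
            # wobble/mismatch choice; retry with fresh random placements
            site = None
            bulge_len = 0
            for attempt in range(400):
                cand = _target_site(mseq, rule, rng if attempt else None)
                a = duplex_mod.align_duplex(mseq, cand, mid, host.transcript_id)
                if rule is None:
                    ok = a.allen_score <= 7.0 and a.mfe_ratio > 0.65
                elif rule == "allen":
                    ok = a.allen_score > 7.0 and a.mfe_ratio > 0.65
                else:  # mfe_ratio
                    ok = a.allen_score <= 7.0 and a.mfe_ratio <= 0.65
                if ok:
                    site = cand
                    break
            if site is None:
                raise ConstructionError(
                    f"could not construct target site (rule={rule}) for {mid}"
                )
        else:
            # the aligner may discover a cheaper off-centre geometry for an
            # unlucky insertion; retry with fresh insertion nucleotides
            site = aln = None
            bulge_len = 0
            for _ in range(400):
                bulge_len = int(rng.integers(1, 6))
                cand = _mimic_site(mseq, rng, bulge_len, rule)
                a = duplex_mod.align_duplex(mseq, cand, mid, host.transcript_id)
                call = mimic_mod.etm_check(a)
                want = "none" if rule is None else rule
                if call.fail_reason == want:
                    site, aln = cand, a
                    break
            if site is None:
                raise ConstructionError(
                    f"could not construct mimic site (rule={rule}) for {mid}"
                )
        start = int(rng.integers(3, host.spliced_length - len(site) - 3))
        _write_site(gbuf, host, start, site)
        aln = duplex_mod.align_duplex(
            mseq, site, mid, host.transcript_id, site_start=start
        )
        if mode == "target":
            qualifies = aln.allen_score <= 7.0 and aln.mfe_ratio > 0.65
            if rule is None and not qualifies:
                raise ConstructionError(
                    f"planted target on {host.transcript_id} does not qualify"
                )
            if rule == "allen" and not (
                aln.allen_score > 7.0 and aln.mfe_ratio > 0.65
            ):
                raise ConstructionError("allen decoy failed construction")
            if rule == "mfe_ratio" and not (
                aln.allen_score <= 7.0 and aln.mfe_ratio <= 0.65
            ):
                raise ConstructionError("mfe_ratio decoy failed construction")
            expect_pass = rule is None
        else:
            call = mimic_mod.etm_check(aln)
            expect_pass = rule is None
            if expect_pass and call.verdict != "pass":
                raise ConstructionError(
                    f"planted mimic on {host.transcript_id} fails: "
                    f"{call.fail_reason}"
                )
            if rule is not None and call.fail_reason != rule:
                raise ConstructionError(
                    f"mimic decoy for rule {rule} fails as {call.fail_reason}"
                )
        rows.append(
            dict(
                mirna_id=mid,
                transcript_id=host.transcript_id,
                site_start=start,
                site_end=start + len(site),
                mode=mode,
                decoy_rule=rule or "none",
                expect_pass=expect_pass,
                allen_score=aln.allen_score,
                mfe_ratio=round(aln.mfe_ratio, 6),
                bulge_length=bulge_len,
            )
        )
    truth = pd.DataFrame(rows)
    return gbuf.decode(), truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def simulate_counts(
    scenario: SyntheticScenario,
    feature_ids: Sequence[str],
    salt: int = 5,
    de_fraction: Optional[float] = None,
    mu_range: Tuple[float, float] = (20.0, 2000.0),
    de_ids: Optional[Sequence[str]] = None,
) -> Tuple[CountMatrix, pd.DataFrame]:
    """NB counts for two groups of n_samples_per_group replicates.

    A de_fraction of features get their treated-group mean multiplied by
    2**planted_log2fc with a random sign; features named in de_ids are
    always planted as differential.  Ground truth lists the per-feature
    baseline mean and planted log2 fold change.
    """
    if scenario.dispersion <= 0:
        raise InputError("dispersion must be positive")
    if scenario.n_samples_per_group < 2:
        raise InputError("need at least 2 replicates per group")
    rng = scenario.rng(salt)
    n = len(feature_ids)
    frac = scenario.de_fraction if de_fraction is None else de_fraction
    mu = np.exp(
        rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]), size=n)
    )
    if (mu <= 0).any():
        raise InputError("non-positive feature means")
    lfc = np.zeros(n)
    if frac > 0 and scenario.planted_log2fc != 0:
        n_de = int(round(frac * n))
        idx = rng.choice(n, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        lfc[idx] = scenario.planted_log2fc * signs
    if de_ids and scenario.planted_log2fc != 0:
        forced = [list(feature_ids).index(i) for i in de_ids]
        signs = rng.choice([-1.0, 1.0], size=len(forced))
        lfc[forced] = scenario.planted_log2fc * signs
        # forced features get a comfortably estimable baseline
        mu[forced] = np.maximum(mu[forced], 200.0)
    r = 1.0 / scenario.dispersion
    nrep = scenario.n_samples_per_group
    samples = [f"CTRL_{i + 1}" for i in range(nrep)] + [
        f"NaCl_{i + 1}" for i in range(nrep)
    ]
    groups = {s: ("control" if s.startswith("CTRL") else "treated") for s in samples}
    mat = np.empty((n, 2 * nrep), dtype=np.int64)
    for j in range(nrep):
        mat[:, j] = rng.negative_binomial(r, r / (r + mu))
    mu_t = mu * np.exp2(lfc)
    for j in range(nrep):
        mat[:, nrep + j] = rng.negative_binomial(r, r / (r + mu_t))
    counts = pd.DataFrame(mat, index=list(feature_ids), columns=samples)
    counts.index.name = "feature_id"
    truth = pd.DataFrame(
        {"feature_id": list(feature_ids), "mu": mu, "log2fc": lfc}
    )
    return CountMatrix(counts=counts, groups=groups), truth


# ---------------------------------------------------------------------------
# Back-splice reads
# ---------------------------------------------------------------------------


def simulate_backsplice_reads(
    scenario: SyntheticScenario,
    junctions: Optional[Sequence[Tuple[str, int, int, int, int]]] = None,
    segment_length: int = 25,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Chimeric-segment records for planted junctions.

    Each junction is (chrom, donor, acceptor, n_reads, n_mismatches) with
    donor > acceptor; every read is emitted as a two-segment record whose 3'
    segment (seg2) maps upstream of its 5' segment (seg1).  Ground truth
    marks whether the junction satisfies the acceptance criteria, with the
    failing rule named.
    """
    junctions = list(junctions if junctions is not None else scenario.planted_junctions)
    rows = []
    truth = []
    for jidx, (chrom, donor, acceptor, n_reads, n_mm) in enumerate(junctions):
        if donor <= acceptor:
            raise InputError(
                f"junction {jidx}: donor must lie downstream of acceptor"
            )
        if n_reads < 0:
            raise InputError(f"junction {jidx}: n_reads must be >= 0")
        span = donor - acceptor
        if n_reads == 0:
            verdict = "undetectable"
        elif n_mm > circ_mod.MAX_MISMATCHES:
            verdict = "reject: mismatches"
        elif span >= circ_mod.MAX_SPAN:
            verdict = "reject: span"
        else:
            verdict = "accept"
        truth.append(
            dict(
                chrom=chrom,
                acceptor=acceptor,
                donor=donor,
                n_reads=n_reads,
                n_mismatches=n_mm,
                span=span,
                verdict=verdict,
            )
        )
        for ridx in range(n_reads):
            rows.append(
                dict(
                    read_id=f"read_j{jidx}_{ridx}",
                    chrom=chrom,
                    seg1_start=donor - segment_length,
                    seg1_end=donor,
                    seg2_start=acceptor,
                    seg2_end=acceptor + segment_length,
                    strand="+",
                    mismatches=n_mm,
                )
            )
    return (
        pd.DataFrame(rows, columns=circ_mod.CHIMERIC_COLUMNS),
        pd.DataFrame(truth),
    )


def default_junctions(
    scenario: SyntheticScenario,
    transcripts: Sequence[TranscriptModel],
    n_total: Optional[int] = None,
) -> List[Tuple[str, int, int, int, int]]:
    """A mixed planted-junction set: exonic / ciRNA / intergenic acceptors
    plus one violation of each acceptance rule."""
    rng = scenario.rng(6)
    n_total = n_total if n_total is not None else scenario.n_circ
    multi = [
        t
        for t in transcripts
        if t.biotype == "mRNA" and len(t.exons) >= 3 and t.strand == "+"
    ]
    if len(multi) < 3:
        raise SizingError("need >=3 multi-exon plus-strand mRNAs for junctions")
    out: List[Tuple[str, int, int, int, int]] = []
    kinds = ["exonic", "ciRNA", "intergenic"]
    occupied_end = max(t.end for t in transcripts)
    for k in range(n_total):
        kind = kinds[k % 3]
        t = multi[(k // 3) % len(multi)]
        if kind == "exonic":
            i = int(rng.integers(0, len(t.exons) - 1))
            j = int(rng.integers(i + 1, len(t.exons)))
            acceptor, donor = t.exons[i][0], t.exons[j][1]
        elif kind == "ciRNA":
            intr = t.introns[int(rng.integers(0, len(t.introns)))]
            pad = max(1, (intr[1] - intr[0]) // 10)
            acceptor, donor = intr[0] + pad, intr[1] - pad
            if donor <= acceptor:
                acceptor, donor = intr[0], intr[1]
        else:
            base = occupied_end + 5_000 + 600 * k
            acceptor, donor = base, base + int(rng.integers(200, 500))
        n_reads = int(rng.integers(1, 8))
        n_mm = int(rng.integers(0, 3))
        out.append((scenario.chrom, donor, acceptor, n_reads, n_mm))
    # rule violations: too many mismatches, zero support, excessive span
    base = occupied_end + 60_000
    out.append((scenario.chrom, base + 300, base, 3, 3))
    out.append((scenario.chrom, base + 2_300, base + 2_000, 0, 0))
    far = scenario.chrom_length - 5_000
    out.append((scenario.chrom, far, far - 150_000, 2, 0))
    return out


# ---------------------------------------------------------------------------
# Complete fixture
# ---------------------------------------------------------------------------


def build_fixture(
    scenario: SyntheticScenario,
    outdir: str,
    n_target_pos: int = 10,
    n_target_decoy: int = 10,
    n_mimic_pos: int = 10,
    n_mimic_decoy: int = 10,
) -> dict:
    """Generate and write a complete pipeline fixture with ground truth.

    Writes genome.fa, annotation.gtf, mirnas.fa, per-class counts TSVs,
    coding-potential scores.tsv, chimeric.tsv and truth/*.tsv + truth.json.
    Returns the ground-truth bundle as a dict of DataFrames/objects.
    """
    import os

    from . import io as io_mod
    from . import lncrna as lnc_mod

    os.makedirs(outdir, exist_ok=True)
    truth_dir = os.path.join(outdir, "truth")
    os.makedirs(truth_dir, exist_ok=True)

    transcripts, genome = make_annotation(scenario)
    mirnas = make_mirnas(scenario)

    # an extra candidate that exactly duplicates an mRNA exon (same strand)
    # exercises the overlap-removal rule
    first_mrna = next(t for t in transcripts if t.biotype == "mRNA")
    overlap_cand = TranscriptModel(
        transcript_id="lnc_overlap",
        gene_id="lnc_overlap",
        chrom=first_mrna.chrom,
        strand=first_mrna.strand,
        exons=(first_mrna.exons[0],),
        biotype="lncRNA_candidate",
    )
    transcripts = list(transcripts) + [overlap_cand]

    genome, target_truth = plant_duplex_sites(
        scenario, transcripts, genome, mirnas, "target", n_target_pos, n_target_decoy
    )
    genome, mimic_truth = plant_duplex_sites(
        scenario, transcripts, genome, mirnas, "mimic", n_mimic_pos, n_mimic_decoy
    )

    junctions = default_junctions(scenario, transcripts)
    chimeric, junction_truth = simulate_backsplice_reads(scenario, junctions)

    # plant positive mimic sites on up to three accepted intergenic circRNAs
    rng = scenario.rng(7)
    mir_ids = sorted(mirnas)
    circ_mimic_rows = []
    accepted = junction_truth[junction_truth["verdict"] == "accept"]
    mrna_spans = [
        t.span for t in transcripts if t.biotype != "lncRNA_candidate"
    ]
    n_planted_circ = 0
    for rec in accepted.to_dict("records"):
        if n_planted_circ >= 3:
            break
        a, d = int(rec["acceptor"]), int(rec["donor"])
        if any(s < d and a < e for s, e in mrna_spans):
            continue  # only intergenic circles are edited directly
        mid = mir_ids[n_planted_circ % len(mir_ids)]
        mseq = mirnas[mid]
        site = None
        for _ in range(400):
            cand = _mimic_site(mseq, rng, int(rng.integers(1, 6)), None)
            a_try = duplex_mod.align_duplex(mseq, cand, mid, "circ")
            if mimic_mod.etm_check(a_try).verdict == "pass":
                site = cand
                break
        if site is None:
            raise ConstructionError("could not construct circRNA mimic site")
        offset = int(rng.integers(5, d - a - len(site) - 5))
        gbuf = bytearray(genome.encode())
        pseudo = TranscriptModel(
            transcript_id="tmp",
            gene_id="tmp",
            chrom=rec["chrom"],
            strand="+",
            exons=((a, d),),
            biotype="other",
        )
        _write_site(gbuf, pseudo, offset, site)
        genome = gbuf.decode()
        aln = duplex_mod.align_duplex(mseq, site, mid, "circ", site_start=offset)
        call = mimic_mod.etm_check(aln)
        if call.verdict != "pass":
            raise ConstructionError("planted circRNA mimic fails eTM check")
        circ_id = f"circ_{rec['chrom']}_{a}_{d}_+"
        circ_mimic_rows.append(
            dict(
                mirna_id=mid,
                transcript_id=circ_id,
                site_start=offset,
                site_end=offset + len(site),
                mode="mimic",
                decoy_rule="none",
                expect_pass=True,
                allen_score=aln.allen_score,
                mfe_ratio=round(aln.mfe_ratio, 6),
                bulge_length=0,
            )
        )
        n_planted_circ += 1
    circ_mimic_truth = pd.DataFrame(circ_mimic_rows, columns=mimic_truth.columns)

    # coding-potential scores: candidates are low-coding-potential except a
    # handful of single-rule filter decoys (never the mimic hosts)
    cands = [t for t in transcripts if t.biotype == "lncRNA_candidate"]
    mimic_hosts = set(mimic_truth["transcript_id"])
    free = [
        c.transcript_id
        for c in cands
        if c.transcript_id not in mimic_hosts
        and c.transcript_id != "lnc_overlap"
        and c.spliced_length >= 200
    ]
    filter_decoys = {}
    for rule, tid in zip(("coverage", "cpc", "cnci"), free):
        filter_decoys[tid] = rule
    score_rows = []
    for c in sorted(cands, key=lambda t: t.transcript_id):
        cov = float(np.round(rng.uniform(5, 50), 2))
        cpc = float(np.round(rng.uniform(-2.0, 0.3), 3))
        cnci = float(np.round(rng.uniform(-2.0, -0.05), 3))
        rule = filter_decoys.get(c.transcript_id)
        if rule == "coverage":
            cov = 1.0
        elif rule == "cpc":
            cpc = 2.5
        elif rule == "cnci":
            cnci = 1.2
        score_rows.append(
            dict(
                transcript_id=c.transcript_id,
                cpc_score=cpc,
                cnci_score=cnci,
                coverage=cov,
            )
        )
    scores = pd.DataFrame(score_rows)

    # counts per RNA class; interaction participants are forced differential
    mrna_ids = sorted(
        t.transcript_id for t in transcripts if t.biotype == "mRNA"
    )
    lnc_ids = sorted(t.transcript_id for t in cands)
    target_pos = target_truth[target_truth["expect_pass"]]
    mimic_pos = mimic_truth[mimic_truth["expect_pass"]]
    de_mirnas = sorted(
        set(target_pos["mirna_id"])
        | set(mimic_pos["mirna_id"])
        | set(circ_mimic_truth["mirna_id"])
    )
    cm_mrna, truth_mrna = simulate_counts(
        scenario, mrna_ids, salt=10, de_ids=sorted(set(target_pos["transcript_id"]))
    )
    cm_lnc, truth_lnc = simulate_counts(
        scenario, lnc_ids, salt=11, de_ids=sorted(set(mimic_pos["transcript_id"]))
    )
    cm_mir, truth_mir = simulate_counts(
        scenario, sorted(mirnas), salt=12, de_ids=de_mirnas
    )
    circ_ids = sorted(
        f"circ_{r['chrom']}_{int(r['acceptor'])}_{int(r['donor'])}_+"
        for r in accepted.to_dict("records")
    )
    cm_circ, truth_circ = simulate_counts(
        scenario,
        circ_ids,
        salt=13,
        mu_range=(20.0, 200.0),
        de_ids=sorted(set(circ_mimic_truth["transcript_id"])),
    )

    io_mod.write_fasta(os.path.join(outdir, "genome.fa"), {scenario.chrom: genome})
    io_mod.write_gtf(os.path.join(outdir, "annotation.gtf"), transcripts)
    io_mod.write_fasta(os.path.join(outdir, "mirnas.fa"), mirnas)
    io_mod.write_counts(os.path.join(outdir, "counts_mrna.tsv"), cm_mrna.counts)
    io_mod.write_counts(os.path.join(outdir, "counts_lncrna.tsv"), cm_lnc.counts)
    io_mod.write_counts(os.path.join(outdir, "counts_mirna.tsv"), cm_mir.counts)
    io_mod.write_counts(os.path.join(outdir, "counts_circrna.tsv"), cm_circ.counts)
    io_mod.write_table(os.path.join(outdir, "scores.tsv"), scores)
    io_mod.write_table(os.path.join(outdir, "chimeric.tsv"), chimeric)

    all_mimic_truth = pd.concat([mimic_truth, circ_mimic_truth], ignore_index=True)
    io_mod.write_table(os.path.join(truth_dir, "targets.tsv"), target_truth)
    io_mod.write_table(os.path.join(truth_dir, "mimics.tsv"), all_mimic_truth)
    io_mod.write_table(os.path.join(truth_dir, "junctions.tsv"), junction_truth)
    for name, df in (
        ("de_mrna", truth_mrna),
        ("de_lncrna", truth_lnc),
        ("de_mirna", truth_mir),
        ("de_circrna", truth_circ),
    ):
        io_mod.write_table(os.path.join(truth_dir, f"{name}.tsv"), df)
    meta = dict(
        seed=scenario.seed,
        filter_decoys=filter_decoys,
        overlap_decoy="lnc_overlap",
        n_lncrna_candidates=len(cands),
        n_accepted_junctions=int((junction_truth["verdict"] == "accept").sum()),
    )
    with open(os.path.join(truth_dir, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)

    return dict(
        transcripts=transcripts,
        genome=genome,
        mirnas=mirnas,
        targets=target_truth,
        mimics=all_mimic_truth,
        junctions=junction_truth,
        de_truth=dict(
            mRNA=truth_mrna, lncRNA=truth_lnc, miRNA=truth_mir, circRNA=truth_circ
        ),
        meta=meta,
    )


def make_network_fixture(seed: int = 0, n_mirna: int = 8, n_mrna: int = 20,
                         n_lnc: int = 8, n_circ: int = 5):
    """A planted ceRNA adjacency (DE tables + edge tables) with known
    edges, triples, hubs and sponges, for exercising network assembly."""
    rng = np.random.default_rng(seed)
    mirnas = [f"miR{i:02d}" for i in range(n_mirna)]
    mrnas = [f"m{i:02d}" for i in range(n_mrna)]
    lncs = [f"l{i:02d}" for i in range(n_lnc)]
    circs = [f"c{i:02d}" for i in range(n_circ)]

    def de_table(ids, frac_ns=0.25):
        status = [
            "ns" if rng.random() < frac_ns else rng.choice(["up", "down"])
            for _ in ids
        ]
        return pd.DataFrame({"status": status}, index=pd.Index(ids, name="feature_id"))

    de = {
        "miRNA": de_table(mirnas),
        "mRNA": de_table(mrnas),
        "lncRNA": de_table(lncs),
        "circRNA": de_table(circs),
    }
    t_rows, m_rows = [], []
    for m in mirnas:
        for t in rng.choice(mrnas, size=rng.integers(1, 8), replace=False):
            t_rows.append(dict(mirna_id=m, target_id=t,
                               allen_score=float(rng.integers(0, 15)) / 2,
                               mfe_ratio=round(float(rng.uniform(0.5, 1.0)), 3)))
        for n in rng.choice(lncs + circs, size=rng.integers(0, 5), replace=False):
            m_rows.append(dict(mirna_id=m, ncrna_id=n, bulge_length=int(rng.integers(1, 6)),
                               allen_score=float(rng.integers(2, 20)) / 2))
    targets = pd.DataFrame(t_rows)
    mimics = pd.DataFrame(m_rows)

    de_ids = {cls: set(df[df["status"] != "ns"].index) for cls, df in de.items()}
    exp_edges = set()
    for r in t_rows:
        if r["mirna_id"] in de_ids["miRNA"] and r["target_id"] in de_ids["mRNA"]:
            exp_edges.add(tuple(sorted((r["mirna_id"], r["target_id"]))))
    for r in m_rows:
        if r["mirna_id"] in de_ids["miRNA"] and (
            r["ncrna_id"] in de_ids["lncRNA"] or r["ncrna_id"] in de_ids["circRNA"]
        ):
            exp_edges.add(tuple(sorted((r["mirna_id"], r["ncrna_id"]))))
    return de, targets, mimics, exp_edges
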