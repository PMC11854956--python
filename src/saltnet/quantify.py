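"""Count normalisation and two-group differential expression.

Normalisation units:
  FPKM  = reads * 1e9 / (feature_length * library_size)
  CPM   = reads * 1e6 / library_size
  SRPBM = back-splice junction reads * 1e9 / mapped reads

Differential expression uses a negative-binomial exact test conditioned on
the per-feature total after scaling all samples to a common library size,
with one common dispersion estimated across features by moments.  The
log2 fold change is computed on mean CPM with a 0.5 pseudocount.  The
significance rule is |log2FC| >= 1 combined with raw p < 0.05 for mRNA,
circRNA and miRNA, but with BH FDR < 0.05 for lncRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .models import CountMatrix, InputError, NormalizationError

LFC_THRESHOLD = 1.0
ALPHA = 0.05
PSEUDOCOUNT_CPM = 0.5
MIN_TOTAL_COUNT = 10

#: per-RNA-class significance rule: True -> BH FDR < alpha, False -> raw p
USE_FDR_BY_CLASS = {"mRNA": False, "lncRNA": True, "circRNA": False, "miRNA": False}


def cpm(counts: pd.DataFrame, library_sizes: Dict[str, int]) -> pd.DataFrame:
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if (libs <= 0).any():
        raise NormalizationError("zero library size")
    return counts * 1e6 / libs


def fpkm(
    counts: pd.DataFrame,
    effective_lengths: Dict[str, int],
    library_sizes: Dict[str, int],
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped reads."""
    lens = pd.Series(effective_lengths).reindex(counts.index)
    if lens.isna().any() or (lens <= 0).any():
        raise InputError("every feature needs a positive effective length")
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if (libs <= 0).any():
        raise NormalizationError("zero library size")
    return counts.mul(1e9, axis=0).div(lens, axis=0).div(libs, axis=1)


def srpbm(junction_reads: float, mapped_reads: float) -> float:
    """Split (back-splice junction) reads per billion mapped reads."""
    if mapped_reads <= 0:
        raise NormalizationError("mapped_reads must be positive")
    if junction_reads < 0:
        raise InputError("junction_reads must be non-negative")
    return junction_reads * 1e9 / mapped_reads


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (stable ordering)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def estimate_common_dispersion(
    scaled: np.ndarray, group_idx: Sequence[np.ndarray]
) -> float:
    """Moment estimate of the common NB dispersion phi (var = mu + phi*mu^2).

    Within each group, the sample variance v is an unbiased estimate of
    mu + phi*mu^2; pooling (v - m) against m^2 across features in a
    least-squares regression through the origin gives phi.
    """
    num = 0.0
    den = 0.0
    for idx in group_idx:
        if len(idx) < 2:
            raise InputError(
                "dispersion not estimable: need >=2 replicates per group"
            )
        g = scaled[:, idx]
        m = g.mean(axis=1)
        v = g.var(axis=1, ddof=1)
        keep = m >= 1
        num += np.sum((v[keep] - m[keep]) * m[keep] ** 2)
        den += np.sum(m[keep] ** 4)
    if den == 0:
        return 1e-4
    return float(max(num / den, 1e-4))


def nb_exact_pvalue(s1: int, n1: int, s2: int, n2: int, phi: float) -> float:
    """Exact conditional two-sided p-value for group sums s1 vs s2.

    Under a common mean and dispersion phi, each group sum is NB with size
    n_g/phi; conditional on the total t the distribution of s1 is free of
    the mean.  The two-sided p sums the probabilities of all outcomes no
    more probable than the observed one.
    """
    t = s1 + s2
    if t == 0:
        return 1.0
    r1, r2 = n1 / phi, n2 / phi
    x = np.arange(t + 1)
    logw = (
        gammaln(x + r1)
        - gammaln(x + 1)
        + gammaln(t - x + r2)
        - gammaln(t - x + 1)
    )
    logw -= logsumexp(logw)
    obs = logw[s1]
    p = np.exp(logsumexp(logw[logw <= obs + 1e-10]))
    return float(min(p, 1.0))


def de_test(
    cm: CountMatrix,
    rna_class: str = "mRNA",
    use_fdr: Optional[bool] = None,
    alpha: float = ALPHA,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """Two-group differential-expression calls for one RNA class.

    Returns a DataFrame indexed like the counts with columns baseMean_ctrl,
    baseMean_trt (mean CPM), log2FC (treated vs control), p_value, fdr and
    status in {up, down, ns}.  Features with total count below
    MIN_TOTAL_COUNT are reported ns with p = 1 and excluded from the BH
    correction.
    """
    if rna_class not in USE_FDR_BY_CLASS:
        raise InputError(f"unknown RNA class: {rna_class}")
    if use_fdr is None:
        use_fdr = USE_FDR_BY_CLASS[rna_class]
    ctrl = cm.samples("control")
    trt = cm.samples("treated")
    if len(ctrl) < 2 or len(trt) < 2:
        raise InputError(
            "dispersion not estimable: need >=2 replicates per group"
        )
    counts = cm.counts
    libs = np.array([cm.library_sizes[s] for s in counts.columns], dtype=float)
    if (libs <= 0).any():
        raise NormalizationError("zero library size")
    raw = counts.values.astype(float)
    ref = float(np.exp(np.mean(np.log(libs))))
    scaled = raw * (ref / libs)

    cols = list(counts.columns)
    i_ctrl = np.array([cols.index(s) for s in ctrl])
    i_trt = np.array([cols.index(s) for s in trt])

    cpm_mat = raw * (1e6 / libs)
    mean_ctrl = cpm_mat[:, i_ctrl].mean(axis=1)
    mean_trt = cpm_mat[:, i_trt].mean(axis=1)
    log2fc = np.log2(mean_trt + PSEUDOCOUNT_CPM) - np.log2(
        mean_ctrl + PSEUDOCOUNT_CPM
    )

    tested = raw.sum(axis=1) >= MIN_TOTAL_COUNT
    phi = (
        estimate_common_dispersion(scaled[tested], [i_ctrl, i_trt])
        if tested.any()
        else 1e-4
    )

    s_ctrl = np.rint(scaled[:, i_ctrl].sum(axis=1)).astype(np.int64)
    s_trt = np.rint(scaled[:, i_trt].sum(axis=1)).astype(np.int64)
    pvals = np.ones(len(raw))
    for k in np.nonzero(tested)[0]:
        pvals[k] = nb_exact_pvalue(
            int(s_ctrl[k]), len(i_ctrl), int(s_trt[k]), len(i_trt), phi
        )

    fdr = np.ones(len(raw))
    if tested.any():
        # stable rank ties by feature id: index order is the input order
        fdr[tested] = bh_fdr(pvals[tested])

    crit = fdr if use_fdr else pvals
    sig = tested & (crit < alpha) & (np.abs(log2fc) >= lfc_threshold)
    status = np.where(sig & (log2fc > 0), "up", np.where(sig, "down", "ns"))

    out = pd.DataFrame(
        {
            "baseMean_ctrl": mean_ctrl,
            "baseMean_trt": mean_trt,
            "log2FC": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "status": status,
        },
        index=counts.index,
    )
    out.index.name = "feature_id"
    out.attrs["dispersion"] = phi
    out.attrs["rna_class"] = rna_class
    return out
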