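# Methods

This note documents the models implemented in `saltnet`, their parameters,
the scope of the synthetic data generator, the numerical choices made, and
known limitations.

## Differential expression (`saltnet.quantify`)

Counts for each RNA class (mRNA, lncRNA, circRNA, miRNA) are compared
between a control and a NaCl-treated group with equal replicate numbers
(≥ 2 per group required).

- **Normalisation.** Library size factors are each sample's total count
  divided by the geometric mean of totals; CPM uses the raw totals.
- **Dispersion.** One negative-binomial dispersion φ per class, via a
  moment estimator on size-factor-scaled counts: with per-feature scaled
  mean m and variance v, φ = Σ(v − m)m² / Σm⁴ over features with m ≥ 1,
  floored at 10⁻⁴.
- **Test.** For each feature the two group sums of scaled (rounded) counts
  are compared with an exact conditional test: given the total, the
  control-sum distribution follows from two NB(r_g = n_g/φ, same p)
  variables; log probability weights are computed with `gammaln` and
  normalised by `logsumexp`, and the two-sided p-value sums all outcomes no
  more probable than the observed one (tolerance 10⁻¹⁰).
- **Decision rule.** A feature is `up`/`down` when |log2FC| ≥ 1 and its
  p-value is below 0.05 — the Benjamini–Hochberg FDR for lncRNAs, the raw
  p-value for the other classes. log2FC is the ratio of group-mean CPM with
  a 0.5 pseudocount. Features with total raw count < 10 are reported `ns`
  with p = 1 and excluded from the BH correction.

## miRNA–site duplex model (`saltnet.duplex`)

Sites are scored with the plant-style Allen penalty: mismatch 1.0, G:U
wobble 0.5, bulged nucleotide 1.0, each doubled when it falls at miRNA
positions 2–13 (a bulge on the site side is doubled when either flanking
miRNA position is in 2–13). Scores are kept in integer half-units
internally. A global gapped dynamic program over the miRNA and the reverse
complement of the site minimises (penalty, number of bulged nucleotides)
lexicographically. miRNAs must be 18–25 nt; sites may be up to 3 nt shorter
than the miRNA.

Duplex stability uses a simplified nearest-neighbour energy
(`ENERGY_MODEL_VERSION = "saltnet-nn-1"`): a 16-entry, reverse-complement-
symmetric stacking table keyed by the miRNA dinucleotide (−0.93 to
−3.42 kcal/mol) summed over consecutive paired miRNA positions, plus a
+3.0 penalty per internal loop or bulge event; terminal unpaired runs are
free. The reported `mfe_ratio` is the site energy over the energy of a
perfect complement, clamped to [0, 1].

`predict_targets` slides a window of miRNA length + 3 along each
transcript. Candidate windows are screened with a batched semi-global DP
(terminal site overhangs free), which scores each window by its best
contiguous sub-span at the exact Allen threshold; all sub-spans of length
≥ miRNA − 3 inside hit windows are then realigned, and the best site —
lowest Allen score, ties broken by lower energy then 5′-most position — is
reported iff Allen ≤ 7.0 and mfe_ratio > 0.65. Trimming overhangs this way
guarantees an embedded perfect complement scores exactly 0.

## Endogenous target mimics (`saltnet.mimic`)

An eTM site must satisfy, in order of precedence when reporting a failure:

1. all bulges lie on the ncRNA side (`bulge_side`; a site with no bulge
   also fails here),
2. there is exactly one bulge, of 1–5 nt, located between two of the
   middle miRNA positions {9, 10, 11, 12} (`bulge_position`),
3. no mismatch at a middle position (`middle_mismatch`),
4. ≤ 4 mismatches outside the middle (`mismatch_count`),
5. no run of ≥ 3 consecutive mismatches, with bulges not interrupting a
   run (`consecutive_mismatches`).

G:U wobbles count as pairing throughout. `scan_mimics` first applies a
closed-form vectorised superset screen over all windows and gap placements,
then verifies candidates with the full aligner and `etm_check`, keeping
passing sites and collapsing overlaps by (Allen score, 5′-most).

## lncRNA identification (`saltnet.lncrna`)

Filtering applies rules in a fixed order, recording the first failure:
mRNA overlap, spliced length ≥ 200 nt, mean coverage ≥ 3.0, CPC score
< 0.5, CNCI score < 0. Retained lncRNAs are classified by position
relative to mRNAs with precedence x (exonic antisense) > o (exonic sense)
> i (intronic) > j (divergent: opposite strands, 5′ ends ≤ 1000 nt apart,
non-overlapping spans) > u (intergenic). Cis pairs are lncRNA–gene pairs
whose spans lie within 100 kb (inclusive); co-expression is the Pearson
correlation of log2(expression + 1) across samples, undefined (NA) for
constant profiles.

## circRNA detection (`saltnet.circrna`)

Chimeric reads are grouped by (chromosome, acceptor = downstream segment
start, donor = upstream segment end, strand), requiring the acceptor
upstream of the donor. A junction is accepted when at least one supporting
read has ≤ 2 mismatches and the span is < 100,000 nt; rejections report the
first failing rule. Accepted circRNAs are typed exonic (both ends match
annotated exon boundaries within ±2 nt; the enclosed exons define the
circular sequence), ciRNA (contained in a same-strand intron) or
intergenic. Abundance is spliced reads per billion mapped reads (SRPBM).
For mimic scanning the pipeline appends the first bases of the circle to
its 3′ end so junction-crossing sites are visible.

## Network assembly (`saltnet.network`)

Nodes are differentially expressed features with ≥ 1 qualifying edge
(isolated DE features optional). Target edges require a DE miRNA and DE
mRNA; mimic edges a DE miRNA and DE ncRNA. Parallel evidence for a pair is
collapsed to the lowest Allen score. Triples are (miRNA, mRNA, ncRNA)
combinations sharing the miRNA. Hubs are nodes with degree strictly > 6;
sponges are ncRNAs with mimic edges to ≥ 2 distinct miRNAs. Exports: SIF,
GraphML (losslessly re-readable via `read_graphml`) and node/edge TSVs.

## Synthetic data generator (`saltnet.synthio`)

The generator produces a single-chromosome genome (default 2 Mb) with
non-overlapping mRNAs (2–9 exons, mostly > 1 kb spliced) and lncRNA
candidates (1–2 exons, mostly short), miRNAs of 18–25 nt, NB count matrices
(default φ = 0.1, 3 vs 3, planted |log2FC| = 2 on a chosen fraction),
chimeric back-splice reads with controllable mismatch/span violations, and
coding-potential score tables with planted filter decoys. Planted duplex
sites (true target/eTM sites and single-rule-violating decoys) are written
into the genome and verified at build time through the real aligner and
rule checks against their intended labels, with randomised retries when a
construction is ambiguous. miRNA composition is constrained to guarantee a
wobble-only decoy is constructible for every miRNA. All randomness derives
from a single scenario seed, so fixtures and the demo pipeline are
byte-reproducible.

Scope: the generator validates the pipeline's decision rules, not
biological realism — no sequencing-error model, no isoforms, no multi-
chromosome genomes, no GC or mappability bias.

## Numerical choices

- Allen scores use integer half-units in all DPs; floats appear only in
  reported scores, so threshold comparisons are exact.
- The batched window screen and the scalar aligner share one recurrence;
  equality of results is tested directly and against independent
  brute-force oracles.
- Exact-test probabilities are computed in log space (`gammaln`,
  `logsumexp`); two-sided summation uses a 10⁻¹⁰ slack on the observed
  probability to absorb rounding.
- Pearson correlations and variance estimates use standard numpy/scipy
  routines; no custom numerics beyond the DPs.

## Limitations

- The duplex energy model is a deliberately small nearest-neighbour
  approximation (single stack table, flat loop penalty, no dangling ends or
  temperature dependence); `mfe` values are comparable within this model
  only and are versioned via `ENERGY_MODEL_VERSION`.
- The exact conditional NB test assumes a shared per-class dispersion and
  conditions on scaled, rounded group sums; with planted DE in a large
  fraction of the library, size-factor normalisation compresses observed
  fold changes (composition bias), as in any global-scaling normalisation.
- Doubling penalties by miRNA position makes the Allen score direction-
  dependent: reverse-complementing both strands renumbers positions, so
  only the undoubled score and the duplex energy are strand-symmetric.
- lncRNA coding-potential filtering consumes externally supplied CPC/CNCI
  scores; the package does not compute coding potential itself.
- circRNA detection uses pre-aligned chimeric read tables, not raw reads;
  alignment itself is out of scope.
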