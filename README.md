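# saltnet

Construction of competing-endogenous-RNA (ceRNA) networks from
whole-transcriptome sequencing of a salt-stress experiment: differential
expression of mRNAs, lncRNAs, circRNAs and miRNAs, plant-style miRNA target
prediction, endogenous target-mimic (eTM/sponge) detection, back-splice
circRNA calling, and assembly of the resulting miRNA-centred network.

## Scientific problem

Under salt stress, plants reprogram their transcriptome. Part of that
regulation runs through miRNAs, which repress mRNA targets by near-perfect
complementary base pairing. Non-coding RNAs — lncRNAs and circRNAs — can
carry miRNA-binding decoy sites (endogenous target mimics) that sequester a
miRNA and de-repress its mRNA targets. Mapping which ncRNAs sponge which
miRNAs, and which mRNAs those miRNAs target, yields a ceRNA network whose
hubs and sponges are candidate regulators of the stress response.

`saltnet` implements that mapping end to end for a two-condition
(control vs NaCl) replicated RNA-seq design, together with a synthetic data
generator that produces genomes, annotations, reads-level evidence and count
matrices with known ground truth, so every stage can be validated exactly.

## The model

- **Differential expression** (`saltnet.quantify`): counts are modelled as
  negative binomial with a shared per-class dispersion estimated by a
  moment estimator on library-size-scaled counts. Significance for each
  feature is an exact conditional two-sided test on the pair of group sums,
  combined with a |log2 fold change| ≥ 1 rule; lncRNAs use
  Benjamini–Hochberg FDR, the other classes raw p-values (cutoff 0.05).
- **miRNA target prediction** (`saltnet.duplex`): a global gapped alignment
  of the miRNA against candidate sites minimises the Allen penalty
  (mismatch 1, G:U wobble 0.5, bulged nucleotide 1, all doubled at miRNA
  positions 2–13), with ties broken by a simplified nearest-neighbour
  duplex energy. A pair is reported when its best site has Allen score
  ≤ 7 and an energy ratio (site MFE over perfect-complement MFE) > 0.65.
- **Target mimics** (`saltnet.mimic`): an eTM site must carry exactly one
  ncRNA-side bulge of 1–5 nt between two of the middle miRNA positions
  (9–12), perfect pairing across the middle, at most 4 mismatches
  elsewhere, and no run of 3+ consecutive mismatches.
- **lncRNA identification** (`saltnet.lncrna`): candidates are filtered by
  mRNA overlap, length ≥ 200 nt, read coverage ≥ 3, and two coding-potential
  scores; survivors are positionally classified (exonic sense/antisense,
  intronic, divergent, intergenic) and paired with cis genes within 100 kb.
- **circRNAs** (`saltnet.circrna`): back-splice junctions are accepted from
  chimeric reads with ≤ 2 mismatches spanning < 100 kb, typed as exonic,
  intronic (ciRNA) or intergenic, and quantified as spliced reads per
  billion mapping.
- **Network** (`saltnet.network`): nodes are differentially expressed
  features with at least one qualifying edge; target and mimic edges are
  collapsed to their best evidence; miRNA–mRNA–ncRNA triples, hubs
  (degree > 6) and sponges (ncRNAs mimicking ≥ 2 miRNAs) are annotated, and
  the graph is exported as SIF, GraphML and TSV.

Details, parameter values and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic study and run the whole pipeline on it:

```bash
$ saltnet demo --out demo --seed 42
stage: quantify
stage: lncrna
stage: circrna
stage: duplex
stage: mimic
stage: network
{
  "circrna": {
    "n_accepted": 20,
    "n_rejected": 2
  },
  "duplex": {
    "n_target_pairs": 13
  },
  "lncrna": {
    "n_candidates": 41,
    "n_cis_pairs": 440,
    "n_retained": 33
  },
  "mimic": {
    "n_mimic_pairs": 23
  },
  "network": {
    "n_edges": 29,
    "n_nodes": 36,
    "n_triples": 24
  },
  "quantify": {
    "n_de_circRNA": 11,
    "n_de_lncRNA": 24,
    "n_de_mRNA": 25,
    "n_de_miRNA": 10
  }
}
```

`demo/fixture/` holds the generated inputs (genome, GTF, miRNA FASTA, count
matrices, chimeric reads, coding-potential scores) plus `truth/` tables;
`demo/results/` holds every stage's outputs. For example, the first
predicted targets:

```bash
$ head -4 demo/results/targets.tsv
mirna_id  target_id  site_start  site_end  allen_score  mfe     mfe_ratio  pairing
miR001    mRNA0001   1431        1455      0.0          -56.79  1.0        ||||||||||||||||||||||||
miR002    mRNA0002   1359        1381      0.0          -48.02  1.0        ||||||||||||||||||||||
miR002    mRNA0039   431         452       7.0          -32.09  0.668263   o|||||o||o-|||oo||o|x|
```

and the network summary (`demo/results/network_summary.json`) reports one
hub (`miR005`, degree > 6) and two sponges
(`circ_chr1_511613_511897_+` and `lnc0010`, each mimicking ≥ 2 miRNAs).

The same primitives are available from Python:

```python
>>> from saltnet.duplex import align_duplex
>>> aln = align_duplex("UGAAGCUGCCAGCAUGAUCUGA", "UCAGGUCAUGCUGGUAGCUUUA")
>>> aln.allen_score, round(aln.mfe, 2), round(aln.mfe_ratio, 3)
(2.5, -47.03, 1.0)
>>> aln.pairing_string()
'|o|||||o|||||||||o||||'
```

Three G:U wobbles (`o`), two of them inside the doubled core, give
0.5 + 1.0 + 1.0 = 2.5; a perfect stack keeps the energy ratio at 1.0, so
this pair qualifies as a target site. The same duplex fails the eTM check
(`etm_check(aln).fail_reason == 'bulge_side'`) because a mimic site must
contain an ncRNA-side bulge.

To run on your own data, write a YAML config (see `demo/config.yaml` for
the full set of keys) and call `saltnet run --config config.yaml`.
Individual stages are exposed as `saltnet de`, `saltnet targets`,
`saltnet mimics`, `saltnet circ detect` and `saltnet lncrna filter`.

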