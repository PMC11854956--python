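"""End-to-end orchestration: configuration, staged execution, manifest.

The pipeline runs quantify -> lncrna -> circrna -> duplex -> mimic ->
network over declared files only, so any stage can be rerun from the
previous stage's outputs.  A JSON manifest records the seed, input digests
and per-stage record counts; reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import circrna as circ_mod
from . import duplex as duplex_mod
from . import io as io_mod
from . import lncrna as lnc_mod
from . import mimic as mimic_mod
from . import network as net_mod
from . import quantify as quant_mod
from .models import CountMatrix, InputError, to_rna

log = logging.getLogger("saltnet")


@dataclass
class PipelineConfig:
    annotation: str
    genome: str
    mirna_fasta: str
    counts_mrna: str
    counts_lncrna: str
    counts_mirna: str
    counts_circrna: str
    scores: str
    chimeric: str
    outdir: str
    seed: int = 42
    allen_max: float = 7.0
    mfe_ratio_min: float = 0.65
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    use_fdr: Dict[str, bool] = field(
        default_factory=lambda: dict(quant_mod.USE_FDR_BY_CLASS)
    )
    mimic_middle: List[int] = field(default_factory=lambda: [9, 10, 11, 12])
    hub_min_degree: int = net_mod.HUB_MIN_DEGREE
    sponge_min_mirnas: int = net_mod.SPONGE_MIN_MIRNAS
    cis_window: int = lnc_mod.CIS_WINDOW

    _PATH_FIELDS = (
        "annotation",
        "genome",
        "mirna_fasta",
        "counts_mrna",
        "counts_lncrna",
        "counts_mirna",
        "counts_circrna",
        "scores",
        "chimeric",
    )

    def validate(self) -> None:
        for f in self._PATH_FIELDS:
            p = getattr(self, f)
            if not os.path.exists(p):
                raise InputError(f"config path for '{f}' does not exist: {p}")
        if not (0 <= self.alpha <= 1):
            raise InputError("alpha must be in [0, 1]")
        if not (0 <= self.mfe_ratio_min <= 1):
            raise InputError("mfe_ratio_min must be in [0, 1]")
        if self.allen_max < 0:
            raise InputError("allen_max must be non-negative")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_counts(path: str) -> CountMatrix:
    counts = io_mod.read_counts(path)
    groups = {
        s: ("control" if s.upper().startswith("CTRL") else "treated")
        for s in counts.columns
    }
    return CountMatrix(counts=counts, groups=groups)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to
    manifest.json in the output directory)."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest: dict = dict(
        version=__version__,
        seed=cfg.seed,
        inputs={f: _digest(getattr(cfg, f)) for f in cfg._PATH_FIELDS},
        stages={},
    )

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        transcripts = io_mod.read_gtf(cfg.annotation)
        genome = io_mod.read_fasta(cfg.genome)
        chrom_seq = {c: s for c, s in genome.items()}
        mirnas = {k: to_rna(v) for k, v in io_mod.read_fasta(cfg.mirna_fasta).items()}

        # ---- quantify: DE per class -------------------------------------
        st = stage("quantify")
        de: Dict[str, pd.DataFrame] = {}
        for cls, path in (
            ("mRNA", cfg.counts_mrna),
            ("lncRNA", cfg.counts_lncrna),
            ("miRNA", cfg.counts_mirna),
            ("circRNA", cfg.counts_circrna),
        ):
            cm = _load_counts(path)
            res = quant_mod.de_test(
                cm,
                cls,
                use_fdr=cfg.use_fdr.get(cls),
                alpha=cfg.alpha,
                lfc_threshold=cfg.lfc_threshold,
            )
            res.round(6).to_csv(
                os.path.join(cfg.outdir, f"de_{cls.lower()}.tsv"), sep="\t"
            )
            de[cls] = res
            st[f"n_de_{cls}"] = int((res["status"] != "ns").sum())

        # ---- lncRNA filtering / classification / cis --------------------
        st = stage("lncrna")
        cands = [t for t in transcripts if t.biotype == "lncRNA_candidate"]
        mrnas = [t for t in transcripts if t.biotype == "mRNA"]
        score_df = io_mod.read_table(cfg.scores)
        scores = {
            r["transcript_id"]: lnc_mod.CodingPotentialRecord(
                transcript_id=r["transcript_id"],
                cpc_score=float(r["cpc_score"]),
                cnci_score=float(r["cnci_score"]),
                coverage=float(r["coverage"]),
            )
            for r in score_df.to_dict("records")
        }
        retained, filter_log = lnc_mod.filter_lncrna_candidates(cands, scores, mrnas)
        io_mod.write_table(
            os.path.join(cfg.outdir, "lncrna_filter.tsv"), filter_log
        )
        class_rows = [
            dict(
                transcript_id=t.transcript_id,
                class_code=lnc_mod.classify_lncrna_position(t, mrnas),
            )
            for t in retained
        ]
        io_mod.write_table(
            os.path.join(cfg.outdir, "lncrna_classes.tsv"),
            pd.DataFrame(class_rows, columns=["transcript_id", "class_code"]),
        )
        retained_gtf = [
            dataclasses.replace(t, biotype="lncRNA") for t in retained
        ]
        io_mod.write_gtf(os.path.join(cfg.outdir, "lncrna.gtf"), retained_gtf)
        st["n_candidates"] = len(cands)
        st["n_retained"] = len(retained)

        de_lnc_ids = set(de["lncRNA"].index[de["lncRNA"]["status"] != "ns"])
        de_lncs = [t for t in retained if t.transcript_id in de_lnc_ids]
        expr = pd.concat(
            [
                quant_mod.cpm(
                    _load_counts(p).counts,
                    _load_counts(p).library_sizes,
                )
                for p in (cfg.counts_lncrna, cfg.counts_mrna)
            ]
        )
        cis = lnc_mod.cis_targets(de_lncs, mrnas, expr=expr, window=cfg.cis_window)
        io_mod.write_table(os.path.join(cfg.outdir, "cis_pairs.tsv"), cis)
        st["n_cis_pairs"] = len(cis)

        # ---- circRNA -----------------------------------------------------
        st = stage("circrna")
        chimeric = io_mod.read_table(cfg.chimeric)
        junctions, reject_log = circ_mod.detect_backsplice(chimeric)
        for j in junctions:
            j.circ_type, j.n_exons = circ_mod.classify_circ(j, transcripts)
        io_mod.write_table(
            os.path.join(cfg.outdir, "circrna.tsv"),
            pd.DataFrame(
                [
                    dict(
                        chrom=j.chrom,
                        acceptor=j.acceptor,
                        donor=j.donor,
                        circ_id=j.circ_id,
                        junction_reads=j.junction_reads,
                        strand=j.strand,
                        circ_type=j.circ_type,
                        n_exons=j.n_exons,
                    )
                    for j in junctions
                ]
            ),
        )
        io_mod.write_table(
            os.path.join(cfg.outdir, "circrna_rejected.tsv"), reject_log
        )
        circ_cm = _load_counts(cfg.counts_circrna)
        mrna_cm = _load_counts(cfg.counts_mrna)
        srpbm = circ_mod.quantify_circ(
            junctions, circ_cm.counts, mrna_cm.library_sizes
        )
        srpbm.round(4).to_csv(
            os.path.join(cfg.outdir, "circrna_srpbm.tsv"), sep="\t"
        )
        st["n_accepted"] = len(junctions)
        st["n_rejected"] = len(reject_log)

        # ---- duplex target prediction ------------------------------------
        st = stage("duplex")
        mrna_seqs = {
            t.transcript_id: to_rna(t.extract(chrom_seq[t.chrom]))
            for t in mrnas
        }
        targets = duplex_mod.predict_targets(
            mirnas,
            mrna_seqs,
            allen_max=cfg.allen_max,
            mfe_ratio_min=cfg.mfe_ratio_min,
        )
        io_mod.write_table(os.path.join(cfg.outdir, "targets.tsv"), targets)
        st["n_target_pairs"] = len(targets)

        # ---- target mimics ------------------------------------------------
        st = stage("mimic")
        nc_seqs = {
            t.transcript_id: to_rna(t.extract(chrom_seq[t.chrom]))
            for t in retained
        }
        join_margin = max(len(s) for s in mirnas.values()) + 10 if mirnas else 0
        for j in junctions:
            seq = to_rna(circ_mod.circ_sequence(j, transcripts, chrom_seq[j.chrom]))
            if len(seq) > join_margin:
                # expose junction-crossing sites on the circular molecule
                seq = seq + seq[:join_margin]
            nc_seqs[j.circ_id] = seq
        mimics = mimic_mod.scan_mimics(
            mirnas, nc_seqs, middle=frozenset(cfg.mimic_middle)
        )
        io_mod.write_table(os.path.join(cfg.outdir, "mimics.tsv"), mimics)
        st["n_mimic_pairs"] = len(mimics)

        # ---- network -------------------------------------------------------
        st = stage("network")
        net = net_mod.build_network(de, targets, mimics)
        net_mod.annotate_hubs(
            net,
            mirna_hub_min_degree=cfg.hub_min_degree,
            sponge_min_mirnas=cfg.sponge_min_mirnas,
        )
        prefix = os.path.join(cfg.outdir, "network")
        for fmt in ("SIF", "GraphML", "TSV"):
            net_mod.export_network(net, prefix, fmt)
        summary = net.summary()
        with open(os.path.join(cfg.outdir, "network_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        st.update(
            n_nodes=summary["n_nodes"],
            n_edges=summary["n_edges"],
            n_triples=summary["n_triples"],
        )
    except Exception as exc:
        manifest["status"] = "incomplete"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise

    manifest["status"] = "complete"
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_demo(outdir: str, seed: int = 42) -> dict:
    """Generate the synthetic fixture and run the full pipeline on it."""
    from .synthio import SyntheticScenario, build_fixture

    fixture_dir = os.path.join(outdir, "fixture")
    scenario = SyntheticScenario(seed=seed)
    build_fixture(scenario, fixture_dir)
    cfg = PipelineConfig(
        annotation=os.path.join(fixture_dir, "annotation.gtf"),
        genome=os.path.join(fixture_dir, "genome.fa"),
        mirna_fasta=os.path.join(fixture_dir, "mirnas.fa"),
        counts_mrna=os.path.join(fixture_dir, "counts_mrna.tsv"),
        counts_lncrna=os.path.join(fixture_dir, "counts_lncrna.tsv"),
        counts_mirna=os.path.join(fixture_dir, "counts_mirna.tsv"),
        counts_circrna=os.path.join(fixture_dir, "counts_circrna.tsv"),
        scores=os.path.join(fixture_dir, "scores.tsv"),
        chimeric=os.path.join(fixture_dir, "chimeric.tsv"),
        outdir=os.path.join(outdir, "results"),
        seed=seed,
    )
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))
    return run_pipeline(cfg)
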