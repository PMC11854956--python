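"""ceRNA network assembly, hub/sponge annotation and export.

Nodes are differentially expressed entities (miRNA, mRNA, lncRNA, circRNA)
holding at least one qualifying edge; edges link a miRNA to an mRNA
(cleavage target) or to an ncRNA (target mimic).  A ceRNA triple is a
(miRNA, mRNA, ncRNA) pair of edges sharing the miRNA.  A miRNA is a hub
when its degree exceeds 6 ("more than six"); an ncRNA is a sponge when it
carries mimic edges to at least two distinct miRNAs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .models import InputError

HUB_MIN_DEGREE = 6  # strict: degree must exceed this
SPONGE_MIN_MIRNAS = 2


@dataclass
class CeRNANetwork:
    graph: nx.Graph
    triples: List[Tuple[str, str, str]]

    @property
    def nodes(self) -> List[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> Set[Tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def summary(self) -> dict:
        by_class: Dict[str, int] = {}
        for _, d in self.graph.nodes(data=True):
            by_class[d["rna_class"]] = by_class.get(d["rna_class"], 0) + 1
        kinds: Dict[str, int] = {}
        for _, _, d in self.graph.edges(data=True):
            kinds[d["edge_kind"]] = kinds.get(d["edge_kind"], 0) + 1
        return dict(
            n_nodes=self.graph.number_of_nodes(),
            n_edges=self.graph.number_of_edges(),
            n_triples=len(self.triples),
            nodes_by_class=by_class,
            edges_by_kind=kinds,
            hubs=sorted(
                n for n, d in self.graph.nodes(data=True) if d.get("hub")
            ),
            sponges=sorted(
                n for n, d in self.graph.nodes(data=True) if d.get("sponge")
            ),
        )


def _de_ids(de: pd.DataFrame) -> Dict[str, str]:
    sig = de[de["status"] != "ns"]
    return {str(i): str(s) for i, s in zip(sig.index, sig["status"])}


def build_network(
    de_by_class: Dict[str, pd.DataFrame],
    targets: pd.DataFrame,
    mimics: pd.DataFrame,
    ncrna_class: Optional[Dict[str, str]] = None,
    include_isolated: bool = False,
) -> CeRNANetwork:
    """Assemble the differential ceRNA network.

    de_by_class maps each RNA class to a de_test result table (indexed by
    feature id with a `status` column).  Target edges require both the
    miRNA and the mRNA to be differential; mimic edges require the miRNA
    and the ncRNA to be differential.  Multiple sites between one pair
    collapse to a single edge carrying the best-site evidence.
    ncrna_class maps ncRNA ids to lncRNA/circRNA when mimic tables mix both;
    otherwise the id is looked up in the DE tables.
    """
    de_status = {cls: _de_ids(df) for cls, df in de_by_class.items()}
    id_class: Dict[str, str] = {}
    for cls, ids in de_status.items():
        for i in ids:
            if i in id_class:
                raise InputError(f"feature id {i} appears in two RNA classes")
            id_class[i] = cls

    g = nx.Graph()

    def ensure_node(nid: str, cls: str) -> None:
        g.add_node(nid, rna_class=cls, de_status=de_status[cls][nid])

    edges: Dict[Tuple[str, str], dict] = {}
    if len(targets):
        for rec in targets.to_dict("records"):
            m, t = str(rec["mirna_id"]), str(rec["target_id"])
            if m not in de_status.get("miRNA", {}):
                continue
            if t not in de_status.get("mRNA", {}):
                continue
            key = (m, t)
            ev = dict(
                edge_kind="target",
                allen_score=float(rec.get("allen_score", float("nan"))),
                mfe_ratio=float(rec.get("mfe_ratio", float("nan"))),
            )
            old = edges.get(key)
            if old is None or ev["allen_score"] < old["allen_score"]:
                edges[key] = ev
    if len(mimics):
        for rec in mimics.to_dict("records"):
            m, n = str(rec["mirna_id"]), str(rec["ncrna_id"])
            if m not in de_status.get("miRNA", {}):
                continue
            cls = (ncrna_class or {}).get(n)
            if cls is None:
                cls = next(
                    (
                        c
                        for c in ("lncRNA", "circRNA")
                        if n in de_status.get(c, {})
                    ),
                    None,
                )
            if cls is None or n not in de_status.get(cls, {}):
                continue
            key = (m, n)
            ev = dict(
                edge_kind="mimic",
                bulge_length=int(rec.get("bulge_length", 0)),
                allen_score=float(rec.get("allen_score", float("nan"))),
            )
            old = edges.get(key)
            if old is None or ev["allen_score"] < old.get(
                "allen_score", float("inf")
            ):
                edges[key] = ev

    for (m, p), ev in sorted(edges.items()):
        cls_p = id_class[p]
        ensure_node(m, "miRNA")
        ensure_node(p, cls_p)
        g.add_edge(m, p, **ev)

    if include_isolated:
        for cls, ids in de_status.items():
            for i in ids:
                if i not in g:
                    ensure_node(i, cls)

    triples: List[Tuple[str, str, str]] = []
    for m in sorted(n for n, d in g.nodes(data=True) if d["rna_class"] == "miRNA"):
        partners = sorted(g.neighbors(m))
        mrnas = [p for p in partners if g.nodes[p]["rna_class"] == "mRNA"]
        ncrnas = [
            p
            for p in partners
            if g.nodes[p]["rna_class"] in ("lncRNA", "circRNA")
        ]
        triples.extend((m, a, b) for a in mrnas for b in ncrnas)
    return CeRNANetwork(graph=g, triples=triples)


def annotate_hubs(
    net: CeRNANetwork,
    mirna_hub_min_degree: int = HUB_MIN_DEGREE,
    sponge_min_mirnas: int = SPONGE_MIN_MIRNAS,
) -> CeRNANetwork:
    """Flag hub miRNAs (degree strictly greater than the threshold) and
    sponge ncRNAs (mimic edges to at least `sponge_min_mirnas` miRNAs)."""
    g = net.graph
    for n, d in g.nodes(data=True):
        if d["rna_class"] == "miRNA":
            d["hub"] = g.degree(n) > mirna_hub_min_degree
        elif d["rna_class"] in ("lncRNA", "circRNA"):
            n_mirnas = sum(
                1
                for nb in g.neighbors(n)
                if g.nodes[nb]["rna_class"] == "miRNA"
                and g.edges[n, nb]["edge_kind"] == "mimic"
            )
            d["sponge"] = n_mirnas >= sponge_min_mirnas
    return net


def export_network(net: CeRNANetwork, prefix: str, fmt: str) -> List[str]:
    """Write the network as SIF, GraphML or node+edge TSV.

    SIF lines are `mirna<TAB>targets|sponged_by<TAB>partner`.  Returns the
    written paths.
    """
    g = net.graph
    if fmt == "SIF":
        path = f"{prefix}.sif"
        with open(path, "w") as fh:
            for u, v, d in sorted(g.edges(data=True)):
                m, p = (u, v) if g.nodes[u]["rna_class"] == "miRNA" else (v, u)
                rel = "targets" if d["edge_kind"] == "target" else "sponged_by"
                fh.write(f"{m}\t{rel}\t{p}\n")
        return [path]
    if fmt == "GraphML":
        path = f"{prefix}.graphml"
        h = nx.Graph()
        for n, d in g.nodes(data=True):
            h.add_node(
                n,
                rna_class=d["rna_class"],
                de_status=d["de_status"],
                hub=bool(d.get("hub", False)),
                sponge=bool(d.get("sponge", False)),
            )
        for u, v, d in g.edges(data=True):
            attrs = {
                k: v2
                for k, v2 in d.items()
                if v2 == v2 and v2 is not None  # drop NaN evidence
            }
            h.add_edge(u, v, **attrs)
        nx.write_graphml(h, path, named_key_ids=True)
        return [path]
    if fmt == "TSV":
        npath, epath = f"{prefix}_nodes.tsv", f"{prefix}_edges.tsv"
        nrows = [
            dict(
                id=n,
                rna_class=d["rna_class"],
                de_status=d["de_status"],
                hub=bool(d.get("hub", False)),
                sponge=bool(d.get("sponge", False)),
            )
            for n, d in sorted(g.nodes(data=True))
        ]
        pd.DataFrame(nrows).to_csv(npath, sep="\t", index=False)
        erows = []
        for u, v, d in sorted(g.edges(data=True)):
            m, p = (u, v) if g.nodes[u]["rna_class"] == "miRNA" else (v, u)
            erows.append(dict(mirna_id=m, partner_id=p, **d))
        pd.DataFrame(erows).to_csv(epath, sep="\t", index=False)
        return [npath, epath]
    raise InputError(f"unknown export format: {fmt}")


def read_graphml(path: str) -> CeRNANetwork:
    """Round-trip reader for export_network(..., fmt='GraphML')."""
    g = nx.read_graphml(path)
    h = nx.Graph()
    for n, d in g.nodes(data=True):
        h.add_node(n, **d)
    for u, v, d in g.edges(data=True):
        h.add_edge(u, v, **d)
    net = CeRNANetwork(graph=h, triples=[])
    net.triples = _recompute_triples(h)
    return net


def _recompute_triples(g: nx.Graph) -> List[Tuple[str, str, str]]:
    triples = []
    for m in sorted(n for n, d in g.nodes(data=True) if d["rna_class"] == "miRNA"):
        partners = sorted(g.neighbors(m))
        mrnas = [p for p in partners if g.nodes[p]["rna_class"] == "mRNA"]
        ncrnas = [
            p
            for p in partners
            if g.nodes[p]["rna_class"] in ("lncRNA", "circRNA")
        ]
        triples.extend((m, a, b) for a in mrnas for b in ncrnas)
    return triples
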