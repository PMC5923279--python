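"""Relevance networks linking metabolite buckets to digestive-efficiency
traits, with cross-compartment merging and standard-format export.

A relevance network is a bipartite graph: one side holds metabolite-bucket
nodes, the other digestive-efficiency trait nodes; an edge carries the
similarity score of the pair and exists only when |score| exceeds the cutoff
(strictly — a score of exactly ±0.5 draws no edge at the default cutoff).
Per-compartment networks are merged into one global network by dropping
unassigned spectral regions and collapsing the buckets that share a
metabolite label within a compartment onto a single representative node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .io import AssignmentMap
from .spls import SimilarityMatrix

logger = logging.getLogger("metadigest")

COMPARTMENT_ABBREV = {"serum": "S", "ileum": "I", "caecum": "C", "other": "O"}

KIND_BUCKET = "metabolite_bucket"
KIND_TRAIT = "trait"


@dataclass
class RelevanceNetwork:
    """Bipartite bucket-trait graph for one compartment."""

    graph: nx.Graph
    compartment: str | None = None
    merged: bool = False

    @property
    def bucket_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("kind") == KIND_BUCKET]

    @property
    def trait_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d.get("kind") == KIND_TRAIT]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_scores(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["score"] for u, v, d in self.graph.edges(data=True)}


def build_network(sim: SimilarityMatrix, cutoff: float = 0.5,
                  compartment: str | None = None,
                  assignment: AssignmentMap | None = None) -> RelevanceNetwork:
    """Threshold a similarity matrix into a relevance network.

    An edge is drawn for every (bucket, trait) pair with |score| strictly
    greater than ``cutoff``; only the endpoints of surviving edges become
    nodes (no isolated nodes). An empty network is a legal outcome."""
    if not 0.0 <= cutoff < 1.0:
        raise ValueError(f"cutoff must lie in [0, 1), got {cutoff}")
    df = sim.values if isinstance(sim, SimilarityMatrix) else sim
    g = nx.Graph()
    for bucket in df.index:
        for trait in df.columns:
            score = float(df.loc[bucket, trait])
            if abs(score) > cutoff:
                if not g.has_node(bucket):
                    metabolites = (assignment.metabolites_for(bucket)
                                   if assignment else [])
                    g.add_node(bucket, kind=KIND_BUCKET,
                               compartment=compartment or "",
                               metabolites=";".join(metabolites))
                if not g.has_node(trait):
                    g.add_node(trait, kind=KIND_TRAIT, compartment="",
                               metabolites="")
                g.add_edge(bucket, trait, score=score)
    net = RelevanceNetwork(graph=g, compartment=compartment)
    logger.info("relevance network (%s, cutoff %.2g): %d bucket node(s), "
                "%d trait node(s), %d edge(s)", compartment or "?", cutoff,
                len(net.bucket_nodes), len(net.trait_nodes), g.number_of_edges())
    return net


def _max_abs_score(g: nx.Graph, node: str) -> float:
    return max((abs(d["score"]) for _, _, d in g.edges(node, data=True)),
               default=0.0)


def merge_networks(nets: list[RelevanceNetwork],
                   maps: dict[str, AssignmentMap] | None = None) -> RelevanceNetwork:
    """Merge per-compartment relevance networks into a single global network
    without redundancy.

    Unassigned buckets are dropped. Within a compartment, buckets sharing a
    metabolite label collapse onto the bucket with the largest |score| over
    its edges (the representative); parallel edges arising from the collapse
    keep the maximum-|score| edge. Trait nodes are shared across
    compartments. Node ids become "label (S|I|C|O)", which namespaces the
    compartments automatically. Idempotent: merging a merged network again
    changes nothing."""
    comps = [n.compartment for n in nets if not n.merged]
    if len(set(comps)) != len(comps):
        raise ValueError("input networks must come from distinct compartments")
    merged = nx.Graph()
    for net in nets:
        g = net.graph
        # group bucket nodes by (label, compartment); drop unassigned ones
        groups: dict[tuple[str, str], list[str]] = {}
        for node in net.bucket_nodes:
            data = g.nodes[node]
            comp = data.get("compartment") or (net.compartment or "other")
            if net.merged:
                label = data.get("label") or node
            else:
                amap = (maps or {}).get(comp)
                if amap is not None:
                    label = amap.label_for(node)
                else:
                    raw = data.get("metabolites", "")
                    label = " + ".join(s for s in raw.split(";") if s) or None
            if label is None:
                continue
            groups.setdefault((label, comp), []).append(node)
        for (label, comp), members in groups.items():
            rep = max(members, key=lambda b: (_max_abs_score(g, b), b))
            if net.merged:  # carry provenance through repeated merges
                rep = g.nodes[rep].get("representative_bucket", rep)
            abbrev = COMPARTMENT_ABBREV.get(comp, comp[:1].upper() or "O")
            node_id = members[0] if net.merged else f"{label} ({abbrev})"
            if not merged.has_node(node_id):
                merged.add_node(node_id, kind=KIND_BUCKET, compartment=comp,
                                label=label, metabolites=label,
                                representative_bucket=rep)
            for bucket in members:
                for _, trait, d in g.edges(bucket, data=True):
                    if g.nodes[trait].get("kind") != KIND_TRAIT:
                        continue
                    if not merged.has_node(trait):
                        merged.add_node(trait, kind=KIND_TRAIT, compartment="",
                                        metabolites="")
                    if merged.has_edge(node_id, trait):
                        if abs(d["score"]) > abs(merged[node_id][trait]["score"]):
                            merged[node_id][trait]["score"] = d["score"]
                    else:
                        merged.add_edge(node_id, trait, score=d["score"])
    out = RelevanceNetwork(graph=merged, compartment=None, merged=True)
    logger.info("merged network: %d metabolite node(s), %d trait node(s), "
                "%d edge(s)", len(out.bucket_nodes), len(out.trait_nodes),
                merged.number_of_edges())
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

EXPORT_FORMATS = ("sif", "graphml", "tsv")


def export_network(net: RelevanceNetwork, path: str | Path,
                   format: str = "graphml") -> Path:
    """Write the network as SIF (``source<TAB>assoc<TAB>target``), GraphML
    (scores and node attributes preserved; round-trips exactly through
    :func:`read_graphml`), or a TSV edge list with scores."""
    path = Path(path)
    fmt = format.lower()
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {EXPORT_FORMATS}")
    g = net.graph
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in g.edges():
                fh.write(f"{u}\tassoc\t{v}\n")
    elif fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tscore\n")
            for u, v, d in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{d['score']:.17g}\n")
    else:
        nx.write_graphml(g, path)
    return path


def read_graphml(path: str | Path) -> RelevanceNetwork:
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    merged = any(d.get("kind") == KIND_BUCKET and "label" in d
                 for _, d in g.nodes(data=True))
    comps = {d.get("compartment") for _, d in g.nodes(data=True)
             if d.get("kind") == KIND_BUCKET}
    comps.discard("")
    comp = comps.pop() if len(comps) == 1 else None
    return RelevanceNetwork(graph=g, compartment=comp, merged=merged)


def node_attribute_table(net: RelevanceNetwork):
    import pandas as pd

    rows = []
    for n, d in net.graph.nodes(data=True):
        rows.append({"node": n, "kind": d.get("kind", ""),
                     "compartment": d.get("compartment", ""),
                     "metabolites": d.get("metabolites", ""),
                     "degree": net.graph.degree(n),
                     "max_abs_score": _max_abs_score(net.graph, n)})
    cols = ["node", "kind", "compartment", "metabolites", "degree",
            "max_abs_score"]
    return pd.DataFrame(rows, columns=cols).set_index("node")
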