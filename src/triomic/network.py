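"""Tripartite pair–metabolite–pathway network: construction, decomposition, candidates.

Relation links induce an undirected graph over three node types — gene/protein
pairs, metabolites and pathways — with edges only between types (pair–pathway,
metabolite–pathway, pair–metabolite). Entities observed in several treatment
groups merge into a single node; group provenance is kept as node metadata.
Connected components ("subnetworks") are ranked by composition and the
top-ranked component's pairs and metabolites are the candidate biomarkers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .joint_mapping import JointPathwayHit, RelationLink

PAIR, METABOLITE, PATHWAY = "pair", "metabolite", "pathway"


def _pair_node(gene_key: str) -> tuple[str, str]:
    return (PAIR, gene_key)


def _met_node(met_id: str) -> tuple[str, str]:
    return (METABOLITE, met_id)


def _pathway_node(pid: str) -> tuple[str, str]:
    return (PATHWAY, pid)


def iter_relations(all_hits) -> Iterable[RelationLink]:
    """Flatten relation links out of per-group hit lists (mapping or sequence)."""
    hit_lists = all_hits.values() if hasattr(all_hits, "values") else all_hits
    for hits in hit_lists:
        for hit in hits if isinstance(hits, (list, tuple)) else [hits]:
            for rel in hit.relations:
                yield rel


def build_network(relations: Iterable[RelationLink]) -> nx.Graph:
    """Build the tripartite network from relation links (pooled across groups).

    Each link contributes its three pairwise edges; identical entities seen in
    different groups collapse onto one node, accumulating group provenance.
    """
    g = nx.Graph()
    for rel in relations:
        pn = _pair_node(rel.pair.gene_key)
        mn = _met_node(rel.metabolite_id)
        wn = _pathway_node(rel.pathway_id)
        group = str(rel.pair.group)
        if pn not in g:
            g.add_node(pn, node_type=PAIR, label=f"{rel.pair.gene_id}/{rel.pair.protein_id}",
                       gene_id=rel.pair.gene_id, protein_id=rel.pair.protein_id, groups=set())
        if mn not in g:
            g.add_node(mn, node_type=METABOLITE, label=rel.metabolite_id, groups=set())
        if wn not in g:
            g.add_node(wn, node_type=PATHWAY, label=rel.pathway_id, groups=set())
        for n in (pn, mn, wn):
            g.nodes[n]["groups"].add(group)
        g.add_edge(pn, wn)
        g.add_edge(mn, wn)
        g.add_edge(pn, mn)
    return g


def _rank_label(i: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA (spreadsheet-style)."""
    label = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


@dataclass
class Subnetwork:
    """One connected component with its composition counts, labelled by rank."""

    label: str
    pair_nodes: set[tuple[str, str]] = field(default_factory=set)
    metabolite_nodes: set[tuple[str, str]] = field(default_factory=set)
    pathway_nodes: set[tuple[str, str]] = field(default_factory=set)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_nodes)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_nodes)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_nodes)

    @property
    def nodes(self) -> set[tuple[str, str]]:
        return self.pair_nodes | self.metabolite_nodes | self.pathway_nodes


def decompose(g: nx.Graph) -> list[Subnetwork]:
    """Connected components ranked and labelled A, B, ...

    Rank key: metabolites desc, pathways desc, pairs desc, then smallest
    gene key (falling back to the smallest node key for pathologically
    pair-free components) — a total order, so labels are deterministic.
    """
    comps = []
    for nodes in nx.connected_components(g):
        pairs = {n for n in nodes if g.nodes[n]["node_type"] == PAIR}
        mets = {n for n in nodes if g.nodes[n]["node_type"] == METABOLITE}
        pws = {n for n in nodes if g.nodes[n]["node_type"] == PATHWAY}
        comps.append((pairs, mets, pws))

    def key(c):
        pairs, mets, pws = c
        anchor = min(k for _, k in pairs) if pairs else min(k for _, k in (mets | pws))
        return (-len(mets), -len(pws), -len(pairs), anchor)

    comps.sort(key=key)
    return [
        Subnetwork(label=_rank_label(i), pair_nodes=p, metabolite_nodes=m, pathway_nodes=w)
        for i, (p, m, w) in enumerate(comps)
    ]


@dataclass
class BiomarkerSet:
    """Candidate biomarkers: the pairs and metabolites of one subnetwork."""

    gene_ids: tuple[str, ...] = ()
    protein_ids: tuple[str, ...] = ()
    metabolite_ids: tuple[str, ...] = ()
    source_label: Optional[str] = None

    @property
    def empty(self) -> bool:
        return not (self.gene_ids or self.protein_ids or self.metabolite_ids)


def extract_candidates(g: nx.Graph, top: Optional[Subnetwork]) -> BiomarkerSet:
    """Candidate biomarker set from the top-ranked subnetwork.

    An empty network yields an explicit empty set, not an exception.
    """
    if top is None:
        return BiomarkerSet()
    genes = sorted(g.nodes[n]["gene_id"] for n in top.pair_nodes)
    prots = sorted(g.nodes[n]["protein_id"] for n in top.pair_nodes)
    mets = sorted(k for _, k in top.metabolite_nodes)
    return BiomarkerSet(gene_ids=tuple(genes), protein_ids=tuple(prots),
                        metabolite_ids=tuple(mets), source_label=top.label)


def subnetwork_summary(subnets: list[Subnetwork]) -> list[dict]:
    """Composition table, one row per subnetwork in rank order."""
    return [
        {"subnetwork": s.label, "n_pairs": s.n_pairs, "n_metabolites": s.n_metabolites, "n_pathways": s.n_pathways}
        for s in subnets
    ]


def export_network_sif(g: nx.Graph, path) -> None:
    lines = []
    for u, v in sorted(g.edges()):
        a, b = sorted([u, v])
        lines.append(f"{a[0]}:{a[1]}\t{a[0]}-{b[0]}\t{b[0]}:{b[1]}")
    Path(path).write_text("\n".join(sorted(lines)) + ("\n" if lines else ""))


def export_network_graphml(g: nx.Graph, path) -> None:
    h = nx.Graph()
    for n, data in g.nodes(data=True):
        h.add_node(
            f"{n[0]}:{n[1]}",
            node_type=data["node_type"],
            label=data["label"],
            groups=",".join(sorted(data["groups"])),
        )
    for u, v in g.edges():
        h.add_edge(f"{u[0]}:{u[1]}", f"{v[0]}:{v[1]}")
    nx.write_graphml(h, path)


def write_subnetwork_summary(subnets: list[Subnetwork], path) -> None:
    Path(path).write_text(json.dumps(subnetwork_summary(subnets), indent=2) + "\n")
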