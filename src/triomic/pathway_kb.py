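"""Pathway knowledge base: membership sets plus directed reaction graphs.

Each pathway owns a simple directed graph over its member metabolites; edges
are single reaction steps annotated with the genes encoding the catalysing
enzymes (possibly none, for spontaneous or unannotated steps). Reversible
reactions are encoded in the data as two opposed edges — the query code
treats every edge as directed.

The central query is the upstream–downstream relation: a gene sits upstream
of a metabolite in a pathway when some directed path exists whose FIRST edge
is catalysed by that gene and which ends at the metabolite. Multi-hop paths
qualify by default (an enzyme several reaction steps above a metabolite still
controls its pool), with an optional hop bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx

from .errors import FormatError, InputError, ValidationError
from .omics_io import normalize_id

#: distinguished source token marking flux entering a pathway from outside
ENTRY_TOKEN = "@entry"


@dataclass
class Pathway:
    pathway_id: str
    name: str
    member_genes: set[str] = field(default_factory=set)
    member_metabolites: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class ReactionEdge:
    """One directed reaction step inside a pathway."""

    pathway_id: str
    source: str  # metabolite id, or ENTRY_TOKEN
    target: str
    catalyst_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValidationError(f"self-loop edge {self.source!r} in pathway {self.pathway_id!r}")


class PathwayKB:
    """Validated pathway collection with per-pathway reaction graphs."""

    def __init__(self, pathways: Iterable[Pathway] = (), edges: Iterable[ReactionEdge] = ()):
        self.pathways: dict[str, Pathway] = {}
        for p in pathways:
            if not p.pathway_id:
                raise ValidationError("empty pathway id")
            if p.pathway_id in self.pathways:
                raise ValidationError(f"duplicate pathway id {p.pathway_id!r}")
            self.pathways[p.pathway_id] = p
        self._graphs: dict[str, nx.DiGraph] = {pid: nx.DiGraph() for pid in self.pathways}
        self.edges: list[ReactionEdge] = []
        for e in edges:
            self.add_edge(e)

    def add_edge(self, e: ReactionEdge) -> None:
        pw = self.pathways.get(e.pathway_id)
        if pw is None:
            raise ValidationError(f"edge references unknown pathway {e.pathway_id!r}")
        for endpoint in (e.source, e.target):
            if endpoint != ENTRY_TOKEN and endpoint not in pw.member_metabolites:
                raise ValidationError(
                    f"edge endpoint {endpoint!r} is not a member metabolite of pathway {e.pathway_id!r}"
                )
        g = self._graphs[e.pathway_id]
        if g.has_edge(e.source, e.target):
            # parallel edges merge; catalyst sets union
            merged = g[e.source][e.target]["catalysts"] | e.catalyst_genes
            g[e.source][e.target]["catalysts"] = merged
        else:
            g.add_edge(e.source, e.target, catalysts=frozenset(e.catalyst_genes))
        self.edges.append(e)

    def graph(self, pathway_id: str) -> nx.DiGraph:
        if pathway_id not in self._graphs:
            raise ValidationError(f"unknown pathway {pathway_id!r}")
        return self._graphs[pathway_id]

    def __len__(self) -> int:
        return len(self.pathways)

    def pathways_with_gene(self, gene_key: str) -> list[str]:
        return sorted(pid for pid, p in self.pathways.items() if gene_key in p.member_genes)

    def pathways_with_metabolite(self, met_key: str) -> list[str]:
        return sorted(pid for pid, p in self.pathways.items() if met_key in p.member_metabolites)


def load_kb(membership_path, edges_path) -> PathwayKB:
    """Load a KB from a GMT-like membership file and a reaction-edge file.

    Membership rows: ``pathway_id<TAB>name<TAB>member...`` with members
    prefixed ``g:`` (gene) or ``m:`` (metabolite). Edge rows:
    ``pathway_id<TAB>source<TAB>target<TAB>catalysts`` (comma-separated gene
    ids, may be empty). ``#`` lines are comments.
    """
    pathways = list(_parse_membership(membership_path))
    kb = PathwayKB(pathways)
    for e in _parse_edges(edges_path):
        kb.add_edge(e)
    return kb


def _open_lines(path):
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def _parse_membership(path) -> Iterable[Pathway]:
    for lineno, line in _open_lines(path):
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected pathway_id<TAB>name<TAB>members...")
        pid, name, *members = parts
        genes, mets = set(), set()
        for m in members:
            m = m.strip()
            if not m:
                continue
            if m.startswith("g:"):
                genes.add(normalize_id(m[2:], "gene"))
            elif m.startswith("m:"):
                mets.add(normalize_id(m[2:], "metabolite"))
            else:
                raise FormatError(f"{path}:{lineno}: member {m!r} lacks a g:/m: prefix")
        yield Pathway(pathway_id=pid.strip(), name=name.strip(), member_genes=genes, member_metabolites=mets)


def _parse_edges(path) -> Iterable[ReactionEdge]:
    for lineno, line in _open_lines(path):
        parts = line.split("\t")
        if len(parts) not in (3, 4):
            raise FormatError(f"{path}:{lineno}: expected pathway_id<TAB>source<TAB>target[<TAB>catalysts]")
        pid, src, tgt = (p.strip() for p in parts[:3])
        catalysts = frozenset(
            normalize_id(c, "gene") for c in (parts[3].split(",") if len(parts) == 4 else []) if c.strip()
        )
        src_key = src if src == ENTRY_TOKEN else normalize_id(src, "metabolite")
        tgt_key = normalize_id(tgt, "metabolite")
        yield ReactionEdge(pathway_id=pid, source=src_key, target=tgt_key, catalyst_genes=catalysts)


def downstream_with_hops(
    kb: PathwayKB, pathway_id: str, gene_id: str, max_hops: Optional[int] = None
) -> dict[str, int]:
    """Metabolites downstream of `gene_id` in a pathway, with shortest path length.

    A metabolite is downstream when a directed path of length <= max_hops
    (unbounded when None) reaches it and the first traversed edge is
    catalysed by the gene; the returned hop count is the length of the
    shortest such path (>= 1). Empty when the gene is not a pathway member.
    """
    if max_hops is not None and max_hops < 1:
        raise ValidationError(f"max_hops must be >= 1 or None, got {max_hops}")
    gk = normalize_id(gene_id, "gene")
    pw = kb.pathways.get(pathway_id)
    if pw is None:
        raise ValidationError(f"unknown pathway {pathway_id!r}")
    if gk not in pw.member_genes:
        return {}
    g = kb.graph(pathway_id)
    # seeds: targets of edges the gene catalyses, at hop 1
    best: dict[str, int] = {}
    frontier: list[str] = []
    for u, v, data in g.edges(data=True):
        if gk in data["catalysts"] and v != ENTRY_TOKEN:
            if best.get(v, 1 << 30) > 1:
                best[v] = 1
                frontier.append(v)
    hops = 1
    while frontier and (max_hops is None or hops < max_hops):
        hops += 1
        nxt: list[str] = []
        for u in frontier:
            for v in g.successors(u):
                if v != ENTRY_TOKEN and v not in best:
                    best[v] = hops
                    nxt.append(v)
        frontier = nxt
    if max_hops is not None:
        best = {m: h for m, h in best.items() if h <= max_hops}
    return best


def downstream_metabolites(
    kb: PathwayKB, pathway_id: str, gene_id: str, max_hops: Optional[int] = None
) -> set[str]:
    return set(downstream_with_hops(kb, pathway_id, gene_id, max_hops))


def has_upstream_downstream(
    kb: PathwayKB, pathway_id: str, gene_id: str, metabolite_id: str, max_hops: Optional[int] = None
) -> bool:
    """True iff the gene sits upstream of the metabolite within the pathway."""
    mk = normalize_id(metabolite_id, "metabolite")
    return mk in downstream_with_hops(kb, pathway_id, gene_id, max_hops)


def export_sif(kb: PathwayKB, pathway_id: str, path) -> None:
    """Write one pathway's reaction graph as SIF (source, interaction, target)."""
    g = kb.graph(pathway_id)
    lines = []
    for u, v, data in sorted(g.edges(data=True)):
        interaction = ",".join(sorted(data["catalysts"])) or "reaction"
        lines.append(f"{u}\t{interaction}\t{v}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_kb(kb: PathwayKB, membership_path, edges_path) -> None:
    """Emit a KB back to the two-file on-disk format (round-trip counterpart of load_kb)."""
    mem_lines = []
    for pid in sorted(kb.pathways):
        p = kb.pathways[pid]
        members = [f"g:{g}" for g in sorted(p.member_genes)] + [f"m:{m}" for m in sorted(p.member_metabolites)]
        mem_lines.append("\t".join([pid, p.name] + members))
    Path(membership_path).write_text("\n".join(mem_lines) + ("\n" if mem_lines else ""))
    edge_lines = []
    for pid in sorted(kb.pathways):
        g = kb.graph(pid)
        for u, v, data in sorted(g.edges(data=True)):
            edge_lines.append("\t".join([pid, u, v, ",".join(sorted(data["catalysts"]))]))
    Path(edges_path).write_text("\n".join(edge_lines) + ("\n" if edge_lines else ""))
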