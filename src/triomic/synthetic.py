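"""Synthetic multiomics instances with planted, exactly recoverable structure.

The generator emulates the statistical shape of the study design — a
2 dose x 3 time factorial of treatment groups, direction-labelled
differential calls at three omics layers, and pathway graphs in which some
gene/protein pairs sit upstream of differential metabolites — without
simulating raw intensities. Every planted pair, relation and subnetwork is
recorded as ground truth, so the full pipeline can be scored for exact
recovery. Noise entities are drawn so they can never create an unplanned
pair or relation: noise genes/proteins use identifier namespaces disjoint
from each other and from the knowledge base, and noise metabolites are
sampled only from KB metabolites that are not downstream of any planted
gene (an exact filter playing the role of rejection sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError
from .groups import GroupKey, default_groups
from .omics_io import DifferentialRecord, DifferentialTable, build_table
from .pair_screen import GeneProteinPair
from .joint_mapping import RelationLink
from .pathway_kb import Pathway, PathwayKB, ReactionEdge, downstream_with_hops


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_pathways: int = 8
    chain_length_range: tuple[int, int] = (4, 8)
    doses: tuple[float, ...] = (100.0, 200.0)
    times: tuple[float, ...] = (12.0, 24.0, 48.0)
    n_planted_pairs: int = 4
    n_planted_relations: int = 6
    noise_genes: int = 8
    noise_proteins: int = 8
    noise_metabolites: int = 8
    p_direction_flip: float = 0.0
    p_uncatalyzed_step: float = 0.25
    p_branch: float = 0.5

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        lo, hi = self.chain_length_range
        if lo < 2 or hi < lo:
            raise ConfigError(f"chain_length_range must satisfy 2 <= lo <= hi, got {self.chain_length_range}")
        for name in ("n_pathways", "n_planted_pairs", "n_planted_relations",
                     "noise_genes", "noise_proteins", "noise_metabolites"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("p_direction_flip", "p_uncatalyzed_step", "p_branch"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")

    @property
    def groups(self) -> list[GroupKey]:
        return default_groups(self.doses, self.times)


@dataclass
class GroundTruth:
    """What a synthetic instance planted, in pipeline-output vocabulary."""

    pairs: set[GeneProteinPair] = field(default_factory=set)
    relations: set[RelationLink] = field(default_factory=set)
    #: connected components over planted relations: frozensets of typed node keys
    subnetworks: set[frozenset] = field(default_factory=set)


def simulate_kb(config: SimulationConfig) -> PathwayKB:
    """Directed metabolite chains (with optional branches) and gene-catalysed edges."""
    rng = np.random.default_rng(config.seed)
    pathways: list[Pathway] = []
    edges: list[ReactionEdge] = []
    for i in range(config.n_pathways):
        pid = f"sp{i:03d}"
        length = int(rng.integers(config.chain_length_range[0], config.chain_length_range[1] + 1))
        mets = [f"{pid} met{j}" for j in range(length)]
        genes: set[str] = set()
        pw_edges: list[tuple[str, str, frozenset]] = []
        for j in range(length - 1):
            if rng.random() < config.p_uncatalyzed_step:
                cat: frozenset = frozenset()
            else:
                gene = f"{pid}_g{j}"
                genes.add(gene)
                cat = frozenset({gene})
            pw_edges.append((mets[j], mets[j + 1], cat))
        if length >= 3 and rng.random() < config.p_branch:
            src = mets[int(rng.integers(0, length - 1))]
            branch = f"{pid} met_b"
            mets.append(branch)
            gene = f"{pid}_gb"
            genes.add(gene)
            pw_edges.append((src, branch, frozenset({gene})))
        pathways.append(Pathway(pathway_id=pid, name=f"synthetic pathway {i}",
                                member_genes=genes, member_metabolites=set(mets)))
        edges.extend(ReactionEdge(pathway_id=pid, source=s, target=t, catalyst_genes=c)
                     for s, t, c in pw_edges)
    return PathwayKB(pathways, edges)


_MAX_PLANT_ATTEMPTS = 50


def _plan_relations(config, kb, rng, planted):
    """Pick one distinct downstream metabolite per relation, round-robin over pairs.

    Returns the (metabolite, group) plan, or None when the draw runs out of
    unused downstream metabolites (callers redraw the pair selection).
    """
    used_mets: dict[GroupKey, set[str]] = {}
    plan: list[tuple[str, GroupKey]] = []
    order = list(range(len(planted)))
    spins = 0
    while len(plan) < config.n_planted_relations:
        if not order:
            return None
        slot = order[spins % len(order)]
        spins += 1
        pid, gene, group, _ = planted[slot]
        reach = downstream_with_hops(kb, pid, gene)
        used = used_mets.setdefault(group, set())
        avail = sorted(set(reach) - used)
        if not avail:
            order.remove(slot)
            continue
        met = avail[int(rng.integers(0, len(avail)))]
        used.add(met)
        plan.append((met, group))
    return plan


def _catalyzed_genes(kb: PathwayKB, pid: str) -> list[str]:
    g = kb.graph(pid)
    out = set()
    for _, _, data in g.edges(data=True):
        out |= data["catalysts"]
    return sorted(out)


def simulate_tables(
    config: SimulationConfig, kb: PathwayKB
) -> tuple[DifferentialTable, DifferentialTable, DifferentialTable, GroundTruth]:
    """Emit gene/protein/metabolite tables plus the exact planted ground truth.

    Planted pairs are direction-consistent (unless flipped with
    p_direction_flip, which removes the pair — and its relations — from the
    truth); each planted relation places a differential metabolite downstream
    of a planted gene in one pathway of one group.
    """
    rng = np.random.default_rng(config.seed + 1)
    groups = config.groups
    if not groups:
        raise ConfigError("no treatment groups configured")

    # candidate planted genes: catalyse at least one edge with >= 1 downstream metabolite
    candidates: list[tuple[str, str]] = []  # (pathway, gene)
    for pid in sorted(kb.pathways):
        for gene in _catalyzed_genes(kb, pid):
            if downstream_with_hops(kb, pid, gene):
                candidates.append((pid, gene))
    if config.n_planted_pairs > len(candidates):
        raise ConfigError(
            f"cannot plant {config.n_planted_pairs} pairs: only {len(candidates)} catalysing genes in KB"
        )

    # rejection-sampled: a draw whose genes run out of distinct downstream
    # metabolites before all relations are placed is discarded and redrawn
    planted: list[tuple[str, str, GroupKey, str]] = []  # (pathway, gene, group, direction)
    met_plan: list[tuple[str, GroupKey]] = []  # (metabolite, group)
    for attempt in range(_MAX_PLANT_ATTEMPTS):
        idx = rng.choice(len(candidates), size=config.n_planted_pairs, replace=False)
        planted = []
        for k in sorted(idx):
            pid, gene = candidates[k]
            group = groups[int(rng.integers(0, len(groups)))]
            direction = "up" if rng.random() < 0.5 else "down"
            planted.append((pid, gene, group, direction))
        met_plan = _plan_relations(config, kb, rng, planted)
        if met_plan is not None:
            break
    else:
        raise ConfigError(
            f"cannot plant {config.n_planted_relations} relations after {_MAX_PLANT_ATTEMPTS} draws: "
            "downstream metabolites exhausted; enlarge the KB or lower the plant counts"
        )

    gene_recs: list[DifferentialRecord] = []
    prot_recs: list[DifferentialRecord] = []
    met_recs: list[DifferentialRecord] = []
    truth = GroundTruth()

    flipped: set[str] = set()
    for pid, gene, group, direction in planted:
        gene_recs.append(DifferentialRecord(gene, "gene", group, direction))
        prot_dir = direction
        if rng.random() < config.p_direction_flip:
            prot_dir = "down" if direction == "up" else "up"
            flipped.add(gene)
        prot_recs.append(DifferentialRecord(gene.upper(), "protein", group, prot_dir))
        if gene not in flipped:
            truth.pairs.add(GeneProteinPair(gene_id=gene, protein_id=gene.upper(),
                                            group=group, direction=direction))

    for met, group in met_plan:
        met_dir = "up" if rng.random() < 0.5 else "down"
        met_recs.append(DifferentialRecord(met, "metabolite", group, met_dir))

    # close the truth under reachability: when two pairs share a pathway and
    # group, each gene is upstream of the other's planted metabolite too, and
    # those relations are just as real as the directly planted ones
    planted_mets: dict[GroupKey, set[str]] = {}
    for rec in met_recs:
        planted_mets.setdefault(rec.group, set()).add(rec.entity_id)
    for pair in truth.pairs:
        for pid in kb.pathways_with_gene(pair.gene_key):
            reach = downstream_with_hops(kb, pid, pair.gene_key)
            for met in planted_mets.get(pair.group, set()) & set(reach):
                truth.relations.add(RelationLink(pair=pair, metabolite_id=met, pathway_id=pid, hops=reach[met]))

    _add_noise(config, kb, rng, groups, planted, gene_recs, prot_recs, met_recs)

    truth.subnetworks = _planted_components(truth.relations)
    genes_t = build_table("gene", gene_recs)
    prots_t = build_table("protein", prot_recs)
    mets_t = build_table("metabolite", met_recs)
    return genes_t, prots_t, mets_t, truth


def _add_noise(config, kb, rng, groups, planted, gene_recs, prot_recs, met_recs) -> None:
    def rand_group() -> GroupKey:
        return groups[int(rng.integers(0, len(groups)))]

    def rand_dir() -> str:
        return "up" if rng.random() < 0.5 else "down"

    for j in range(config.noise_genes):
        gene_recs.append(DifferentialRecord(f"noise_gene_{j}", "gene", rand_group(), rand_dir()))
    for j in range(config.noise_proteins):
        prot_recs.append(DifferentialRecord(f"NOISE_PROT_{j}", "protein", rand_group(), rand_dir()))

    # exact rejection filter: a noise metabolite must not lie downstream of any
    # planted gene in any pathway, nor duplicate a planted metabolite
    forbidden: set[str] = {r.entity_id for r in met_recs}
    for pid, gene, _, _ in planted:
        for other_pid in kb.pathways_with_gene(gene):
            forbidden |= set(downstream_with_hops(kb, other_pid, gene))
    pool = sorted({m for p in kb.pathways.values() for m in p.member_metabolites} - forbidden)
    if config.noise_metabolites > len(pool):
        raise ConfigError(
            f"cannot draw {config.noise_metabolites} noise metabolites: only {len(pool)} KB metabolites "
            "survive the no-unplanned-relation filter"
        )
    if config.noise_metabolites:
        picks = rng.choice(len(pool), size=config.noise_metabolites, replace=False)
        for k in sorted(picks):
            met_recs.append(DifferentialRecord(pool[k], "metabolite", rand_group(), rand_dir()))


def _planted_components(relations: set[RelationLink]) -> set[frozenset]:
    """Union-find over planted relations — the truth-side mirror of decompose()."""
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        for n in (a, b):
            parent.setdefault(n, n)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for rel in relations:
        pn = ("pair", rel.pair.gene_key)
        mn = ("metabolite", rel.metabolite_id)
        wn = ("pathway", rel.pathway_id)
        union(pn, mn)
        union(pn, wn)
    comps: dict[tuple[str, str], set] = {}
    for n in parent:
        comps.setdefault(find(n), set()).add(n)
    return {frozenset(c) for c in comps.values()}


@dataclass(frozen=True)
class LayerScore:
    precision: float
    recall: float


@dataclass(frozen=True)
class RecoveryReport:
    pairs: LayerScore
    relations: LayerScore
    subnetworks: LayerScore


def _score(predicted: set, truth: set) -> LayerScore:
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0  # no predictions -> vacuous precision
    recall = tp / len(truth) if truth else 1.0
    return LayerScore(precision=precision, recall=recall)


def evaluate_recovery(result, truth: GroundTruth) -> RecoveryReport:
    """Precision/recall of a pipeline result against the planted truth.

    `result` is any object exposing ``pairs`` (GeneProteinPair collection),
    ``relations`` (RelationLink collection) and ``subnetworks`` (Subnetwork
    list); the pipeline's result bundle qualifies.
    """
    import logging

    pred_pairs = set(result.pairs)
    pred_rels = set(result.relations)
    pred_subnets = {frozenset(s.nodes) for s in result.subnetworks}
    if not pred_pairs and truth.pairs:
        logging.getLogger(__name__).warning("no predicted pairs; precision reported as 1.0 by convention")
    return RecoveryReport(
        pairs=_score(pred_pairs, truth.pairs),
        relations=_score(pred_rels, truth.relations),
        subnetworks=_score(pred_subnets, truth.subnetworks),
    )
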