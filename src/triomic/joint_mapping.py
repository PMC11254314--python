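"""Joint pathway mapping of gene/protein pairs and differential metabolites.

Per treatment group, a pathway is a *joint* hit when it contains at least one
consistent pair's gene and at least one differential metabolite of that
group; the hit carries a *relation* when some pair-gene sits upstream of some
differential metabolite along the pathway's reaction graph. Pathway
co-occurrence is decided on the gene — the protein's membership is implied by
its gene, since the knowledge base stores genes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import FormatError, InputError
from .groups import GroupKey, _fmt_num
from .omics_io import DifferentialTable
from .pair_screen import GeneProteinPair
from .pathway_kb import PathwayKB, downstream_with_hops


@dataclass(frozen=True, order=True)
class RelationLink:
    """One upstream–downstream relation: a pair's gene above a metabolite in a pathway."""

    pair: GeneProteinPair
    metabolite_id: str
    pathway_id: str
    hops: int

    def __post_init__(self) -> None:
        if self.hops < 1:
            raise ValueError(f"hops must be >= 1, got {self.hops}")


@dataclass
class JointPathwayHit:
    """A pathway jointly containing pairs and differential metabolites of one group."""

    group: GroupKey
    pathway_id: str
    pairs: set[GeneProteinPair] = field(default_factory=set)
    metabolites: set[str] = field(default_factory=set)
    relations: set[RelationLink] = field(default_factory=set)

    @property
    def has_relation(self) -> bool:
        return bool(self.relations)


@dataclass
class GroupSummary:
    """Per-group integration counts: the three indicators the phenotype is correlated with."""

    group: GroupKey
    n_joint_pathways: int
    n_relation_pathways: int
    n_differential_metabolites: int

    def __post_init__(self) -> None:
        if self.n_relation_pathways > self.n_joint_pathways:
            raise ValueError(
                f"{self.group}: relation pathways ({self.n_relation_pathways}) cannot "
                f"exceed joint pathways ({self.n_joint_pathways})"
            )


def map_group(
    pairs: Sequence[GeneProteinPair],
    metabolites: DifferentialTable,
    kb: PathwayKB,
    group: GroupKey,
    max_hops: Optional[int] = None,
) -> list[JointPathwayHit]:
    """Joint pathway hits for one group, ordered by (|relations| desc, pathway_id).

    Only pairs belonging to `group` are considered, so callers may pass the
    pooled pair list.
    """
    group_pairs = [p for p in pairs if p.group == group]
    diff_mets = metabolites.ids_in_group(group)
    hits: list[JointPathwayHit] = []
    for pid in sorted(kb.pathways):
        pw = kb.pathways[pid]
        member_pairs = {p for p in group_pairs if p.gene_key in pw.member_genes}
        member_mets = diff_mets & pw.member_metabolites
        if not member_pairs or not member_mets:
            continue
        relations: set[RelationLink] = set()
        for pair in member_pairs:
            reach = downstream_with_hops(kb, pid, pair.gene_key, max_hops)
            for met in member_mets & set(reach):
                relations.add(RelationLink(pair=pair, metabolite_id=met, pathway_id=pid, hops=reach[met]))
        hits.append(
            JointPathwayHit(group=group, pathway_id=pid, pairs=member_pairs, metabolites=member_mets, relations=relations)
        )
    hits.sort(key=lambda h: (-len(h.relations), h.pathway_id))
    return hits


def summarize_groups(
    all_hits: Mapping[GroupKey, Sequence[JointPathwayHit]],
    metabolite_table: DifferentialTable,
    groups: Optional[Sequence[GroupKey]] = None,
) -> list[GroupSummary]:
    """One summary per group, in canonical (dose, time) order.

    `groups` fixes the group universe (e.g. all six design cells, including
    cells with no differential entities); by default it is the union of the
    mapped groups and the metabolite table's groups.
    """
    if groups is None:
        groups = sorted(set(all_hits) | set(metabolite_table.groups))
    out = []
    for g in sorted(groups):
        hits = all_hits.get(g, [])
        out.append(
            GroupSummary(
                group=g,
                n_joint_pathways=len(hits),
                n_relation_pathways=sum(1 for h in hits if h.has_relation),
                n_differential_metabolites=len(metabolite_table.ids_in_group(g)),
            )
        )
    return out


_CATALOGUE_COLS = [
    "group",
    "dose_uM",
    "time_h",
    "pathway_id",
    "gene_id",
    "protein_id",
    "pair_direction",
    "metabolite_id",
    "metabolite_direction",
    "hops",
]


def collect_relation_catalogue(
    all_hits: Mapping[GroupKey, Sequence[JointPathwayHit]],
    metabolite_table: Optional[DifferentialTable] = None,
) -> pd.DataFrame:
    """Flatten every relation link into one deterministic table.

    One row per (group, pathway, pair, metabolite); sorted by
    (group, pathway_id, gene_id, metabolite_id) with no duplicate rows.
    """
    rows = []
    for g in sorted(all_hits):
        for hit in all_hits[g]:
            for rel in hit.relations:
                met_dir = (
                    metabolite_table.direction_of(rel.metabolite_id, g) if metabolite_table is not None else None
                )
                rows.append(
                    {
                        "group": str(g),
                        "dose_uM": _fmt_num(g.dose),
                        "time_h": _fmt_num(g.time),
                        "pathway_id": rel.pathway_id,
                        "gene_id": rel.pair.gene_id,
                        "protein_id": rel.pair.protein_id,
                        "pair_direction": rel.pair.direction,
                        "metabolite_id": rel.metabolite_id,
                        "metabolite_direction": met_dir or "",
                        "hops": rel.hops,
                    }
                )
    df = pd.DataFrame(rows, columns=_CATALOGUE_COLS)
    if not df.empty:
        df = (
            df.sort_values(["dose_uM", "time_h", "pathway_id", "gene_id", "metabolite_id"], key=_sort_key)
            .drop_duplicates(subset=["group", "pathway_id", "gene_id", "metabolite_id"])
            .reset_index(drop=True)
        )
    return df


def _sort_key(col: pd.Series) -> pd.Series:
    try:
        return col.astype(float)
    except (TypeError, ValueError):
        return col.astype(str).str.casefold()


def write_group_summaries(summaries: Sequence[GroupSummary], path) -> None:
    rows = [
        {
            "dose_uM": _fmt_num(s.group.dose),
            "time_h": _fmt_num(s.group.time),
            "n_differential_metabolites": s.n_differential_metabolites,
            "n_joint_pathways": s.n_joint_pathways,
            "n_relation_pathways": s.n_relation_pathways,
        }
        for s in sorted(summaries, key=lambda s: s.group)
    ]
    pd.DataFrame(
        rows,
        columns=["dose_uM", "time_h", "n_differential_metabolites", "n_joint_pathways", "n_relation_pathways"],
    ).to_csv(path, sep="\t", index=False)


def read_group_summaries(path) -> list[GroupSummary]:
    """Read per-group indicator counts from TSV (the write_group_summaries layout).

    This also ingests externally tabulated counts, e.g. published per-group
    totals used as correlation inputs.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["dose_uM", "time_h", "n_differential_metabolites", "n_joint_pathways", "n_relation_pathways"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return [
        GroupSummary(
            group=GroupKey(float(r["dose_uM"]), float(r["time_h"])),
            n_joint_pathways=int(r["n_joint_pathways"]),
            n_relation_pathways=int(r["n_relation_pathways"]),
            n_differential_metabolites=int(r["n_differential_metabolites"]),
        )
        for _, r in df.iterrows()
    ]
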