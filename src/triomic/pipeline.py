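"""End-to-end orchestration: screen -> map -> network -> candidates -> correlate.

`run_integration` is the library entry point the analysis scripts, tests and
acceptance machinery all call; `run_all` additionally writes the full report
bundle (pair tables, relation catalogue, group summaries, subnetwork summary,
candidate list, correlation report, SIF/GraphML exports and a run log) to an
output directory. Re-running with identical inputs yields byte-identical
tables; only the log carries a timestamp.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .errors import ConfigError
from .groups import GroupKey
from .omics_io import (
    DifferentialTable,
    PhenotypeSeries,
    read_differential_table,
    read_phenotype_series,
)
from .pair_screen import GeneProteinMap, GeneProteinPair, screen_consistent_pairs, write_pairs
from .pathway_kb import PathwayKB, load_kb
from .joint_mapping import (
    GroupSummary,
    JointPathwayHit,
    collect_relation_catalogue,
    summarize_groups,
    write_group_summaries,
)
from .network import (
    BiomarkerSet,
    Subnetwork,
    build_network,
    decompose,
    export_network_graphml,
    export_network_sif,
    extract_candidates,
    iter_relations,
    subnetwork_summary,
)
from .correlate import CorrelationReport, correlate_dose, correlation_table

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and options for a full run. Flags given on the CLI override file values."""

    genes: Optional[str] = None
    proteins: Optional[str] = None
    metabolites: Optional[str] = None
    kb_membership: Optional[str] = None
    kb_edges: Optional[str] = None
    phenotype: Optional[str] = None
    mapping: Optional[str] = None
    max_hops: Optional[int] = None
    r_threshold: float = 0.8
    abs_r: bool = False
    out: str = "results"

    def __post_init__(self) -> None:
        if self.max_hops is not None and self.max_hops < 1:
            raise ConfigError(f"max_hops must be >= 1 or unset, got {self.max_hops}")
        if not (0.0 <= self.r_threshold <= 1.0):
            raise ConfigError(f"r_threshold must lie in [0, 1], got {self.r_threshold}")


@dataclass
class PipelineResult:
    """Everything one integration run computed, in memory."""

    pairs: list[GeneProteinPair] = field(default_factory=list)
    pair_counts: dict[GroupKey, int] = field(default_factory=dict)
    hits_by_group: dict[GroupKey, list[JointPathwayHit]] = field(default_factory=dict)
    summaries: list[GroupSummary] = field(default_factory=list)
    catalogue: pd.DataFrame = field(default_factory=pd.DataFrame)
    graph: nx.Graph = field(default_factory=nx.Graph)
    subnetworks: list[Subnetwork] = field(default_factory=list)
    candidates: BiomarkerSet = field(default_factory=BiomarkerSet)
    correlations: list[CorrelationReport] = field(default_factory=list)

    @property
    def relations(self):
        return list(iter_relations(self.hits_by_group))


def run_integration(
    genes: DifferentialTable,
    proteins: DifferentialTable,
    metabolites: DifferentialTable,
    kb: PathwayKB,
    phenotype: Optional[PhenotypeSeries] = None,
    mapping: Optional[GeneProteinMap] = None,
    max_hops: Optional[int] = None,
    r_threshold: float = 0.8,
    abs_r: bool = False,
    groups: Optional[Sequence[GroupKey]] = None,
) -> PipelineResult:
    """Run the full integration on in-memory inputs.

    The group universe defaults to the phenotype's groups when a phenotype is
    given (so design cells without differential calls still appear, with
    zero counts), else to the union of the three tables' groups.
    """
    from .joint_mapping import map_group

    if groups is None:
        if phenotype is not None and len(phenotype):
            groups = phenotype.groups
        else:
            groups = sorted(set(genes.groups) | set(proteins.groups) | set(metabolites.groups))
    groups = sorted(groups)

    res = PipelineResult()
    for g in groups:
        found = screen_consistent_pairs(genes, proteins, mapping, g)
        res.pairs.extend(found)
        res.pair_counts[g] = len(found)
        res.hits_by_group[g] = map_group(found, metabolites, kb, g, max_hops=max_hops)
    res.summaries = summarize_groups(res.hits_by_group, metabolites, groups=groups)
    res.catalogue = collect_relation_catalogue(res.hits_by_group, metabolites)
    res.graph = build_network(iter_relations(res.hits_by_group))
    res.subnetworks = decompose(res.graph)
    top = res.subnetworks[0] if res.subnetworks else None
    res.candidates = extract_candidates(res.graph, top)
    if phenotype is not None and len(phenotype):
        for dose in phenotype.doses():
            if len(phenotype.at_dose(dose)) >= 3:
                res.correlations.extend(
                    correlate_dose(phenotype, res.summaries, dose, threshold=r_threshold, absolute=abs_r)
                )
    return res


def load_inputs(cfg: PipelineConfig):
    """Read every configured input file; raises the package's typed errors."""
    if not (cfg.genes and cfg.proteins and cfg.metabolites and cfg.kb_membership and cfg.kb_edges):
        raise ConfigError("genes, proteins, metabolites, kb_membership and kb_edges are all required")
    genes = read_differential_table(cfg.genes, "gene")
    proteins = read_differential_table(cfg.proteins, "protein")
    metabolites = read_differential_table(cfg.metabolites, "metabolite")
    kb = load_kb(cfg.kb_membership, cfg.kb_edges)
    phenotype = read_phenotype_series(cfg.phenotype) if cfg.phenotype else None
    mapping = GeneProteinMap.from_tsv(cfg.mapping) if cfg.mapping else None
    return genes, proteins, metabolites, kb, phenotype, mapping


def write_bundle(res: PipelineResult, outdir, cfg: Optional[PipelineConfig] = None) -> None:
    """Write the full report bundle to `outdir` (created if needed)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_pairs(res.pairs, out / "pairs.tsv")
    (out / "pair_counts.json").write_text(
        json.dumps({str(g): n for g, n in sorted(res.pair_counts.items())}, indent=2) + "\n"
    )
    res.catalogue.to_csv(out / "relation_catalogue.tsv", sep="\t", index=False)
    write_group_summaries(res.summaries, out / "group_summaries.tsv")
    (out / "subnetworks.json").write_text(json.dumps(subnetwork_summary(res.subnetworks), indent=2) + "\n")
    (out / "candidates.json").write_text(
        json.dumps(
            {
                "subnetwork": res.candidates.source_label,
                "genes": list(res.candidates.gene_ids),
                "proteins": list(res.candidates.protein_ids),
                "metabolites": list(res.candidates.metabolite_ids),
            },
            indent=2,
        )
        + "\n"
    )
    correlation_table(res.correlations).to_csv(out / "correlations.tsv", sep="\t", index=False)
    export_network_sif(res.graph, out / "network.sif")
    export_network_graphml(res.graph, out / "network.graphml")
    log_lines = [
        f"triomic {__version__} on python {platform.python_version()}",
        f"finished {datetime.now(timezone.utc).isoformat()}",
        f"config: {cfg}",
        f"pairs={len(res.pairs)} relations={len(res.relations)} subnetworks={len(res.subnetworks)}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")


def run_all(cfg: PipelineConfig) -> PipelineResult:
    """Load inputs, run the full integration, write the bundle. Returns the result."""
    genes, proteins, metabolites, kb, phenotype, mapping = load_inputs(cfg)
    if not (len(genes) or len(proteins) or len(metabolites)):
        log.warning("all differential tables are empty; emitting an empty bundle")
    res = run_integration(
        genes, proteins, metabolites, kb,
        phenotype=phenotype, mapping=mapping,
        max_hops=cfg.max_hops, r_threshold=cfg.r_threshold, abs_r=cfg.abs_r,
    )
    write_bundle(res, cfg.out, cfg)
    return res
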