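"""Access to the bundled worked-example fixtures.

The package ships a transcription of the study's published differential
entities (genes, proteins, metabolites with their directions), the
proliferation phenotype series, the published per-group indicator counts,
and a hand-curated mini pathway knowledge base realising every published
upstream–downstream relation at coarse granularity.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .omics_io import DifferentialTable, PhenotypeSeries, read_differential_table, read_phenotype_series
from .pathway_kb import PathwayKB, load_kb
from .joint_mapping import GroupSummary, read_group_summaries

_FILES = {
    "genes": "table3_genes.tsv",
    "proteins": "table3_proteins.tsv",
    "metabolites": "table3_metabolites.tsv",
    "phenotype": "phenotype.tsv",
    "printed_counts": "printed_group_counts.tsv",
    "kb_membership": "kb_membership.tsv",
    "kb_edges": "kb_edges.tsv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled fixture file (by short name or filename)."""
    fname = _FILES.get(name, name)
    with resources.as_file(resources.files("triomic") / "data" / fname) as p:
        return Path(p)


def load_fixture_tables() -> tuple[DifferentialTable, DifferentialTable, DifferentialTable]:
    return (
        read_differential_table(fixture_path("genes"), "gene"),
        read_differential_table(fixture_path("proteins"), "protein"),
        read_differential_table(fixture_path("metabolites"), "metabolite"),
    )


def load_fixture_kb() -> PathwayKB:
    return load_kb(fixture_path("kb_membership"), fixture_path("kb_edges"))


def load_fixture_phenotype() -> PhenotypeSeries:
    return read_phenotype_series(fixture_path("phenotype"))


def load_printed_counts() -> list[GroupSummary]:
    """The published per-group indicator counts, as correlation inputs."""
    return read_group_summaries(fixture_path("printed_counts"))
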