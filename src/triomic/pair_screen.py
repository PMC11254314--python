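"""Screening of direction-consistent gene/protein pairs.

A gene and its protein product count as a consistent pair in a treatment
group when both are called differential in that group with the same
direction. mRNA and protein changes often disagree; requiring concordance at
both layers filters transcriptional noise before pathway mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import FormatError, InputError, ValidationError
from .groups import GroupKey, _fmt_num
from .omics_io import DifferentialTable, normalize_id


@dataclass(frozen=True, order=True)
class GeneProteinPair:
    """A gene and its encoded protein, both differential in `group` with one direction."""

    gene_id: str
    protein_id: str
    group: GroupKey
    direction: str

    @property
    def gene_key(self) -> str:
        return normalize_id(self.gene_id, "gene")


class GeneProteinMap:
    """Which protein is the product of which gene.

    The default (empty) map pairs identifiers that agree case-insensitively
    (Rrm2 <-> RRM2), the convention mouse gene/protein symbols follow. An
    explicit two-column mapping overrides this and must be one-to-one after
    normalization.
    """

    def __init__(self, pairs: Optional[list[tuple[str, str]]] = None):
        self._g2p: dict[str, str] = {}
        self._p2g: dict[str, str] = {}
        for gene, protein in pairs or []:
            gk = normalize_id(gene, "gene")
            pk = normalize_id(protein, "protein")
            if gk in self._g2p and self._g2p[gk] != pk:
                raise ValidationError(f"gene {gene!r} mapped to two proteins")
            if pk in self._p2g and self._p2g[pk] != gk:
                raise ValidationError(f"protein {protein!r} mapped to two genes")
            self._g2p[gk] = pk
            self._p2g[pk] = gk

    @property
    def explicit(self) -> bool:
        return bool(self._g2p)

    def protein_key_for(self, gene_key: str) -> str:
        """Normalized protein key paired with a normalized gene key."""
        if self.explicit:
            return self._g2p.get(gene_key, "")
        return gene_key  # identity under case-folding

    @classmethod
    def from_tsv(cls, path) -> "GeneProteinMap":
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such mapping file: {path}")
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        missing = [c for c in ("gene_id", "protein_id") if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        return cls(list(zip(df["gene_id"], df["protein_id"])))


def screen_consistent_pairs(
    genes: DifferentialTable,
    proteins: DifferentialTable,
    mapping: Optional[GeneProteinMap],
    group: GroupKey,
) -> list[GeneProteinPair]:
    """All gene/protein pairs differential in `group` with matching direction.

    Returns pairs ordered by gene id; an empty list is a valid result.
    """
    mapping = mapping or GeneProteinMap()
    prot_by_key = {r.key: r for r in proteins.records_in_group(group)}
    out: list[GeneProteinPair] = []
    for grec in genes.records_in_group(group):
        pk = mapping.protein_key_for(grec.key)
        prec = prot_by_key.get(pk)
        if prec is not None and prec.direction == grec.direction:
            out.append(
                GeneProteinPair(
                    gene_id=grec.entity_id,
                    protein_id=prec.entity_id,
                    group=group,
                    direction=grec.direction,
                )
            )
    return sorted(out, key=lambda p: p.gene_key)


def pair_counts_by_group(
    genes: DifferentialTable,
    proteins: DifferentialTable,
    mapping: Optional[GeneProteinMap] = None,
) -> dict[GroupKey, int]:
    """Consistent-pair count for every group present in either table."""
    groups = sorted(set(genes.groups) | set(proteins.groups))
    return {g: len(screen_consistent_pairs(genes, proteins, mapping, g)) for g in groups}


def write_pairs(pairs: list[GeneProteinPair], path) -> None:
    rows = [
        {
            "gene_id": p.gene_id,
            "protein_id": p.protein_id,
            "dose_uM": _fmt_num(p.group.dose),
            "time_h": _fmt_num(p.group.time),
            "direction": p.direction,
        }
        for p in pairs
    ]
    pd.DataFrame(rows, columns=["gene_id", "protein_id", "dose_uM", "time_h", "direction"]).to_csv(
        path, sep="\t", index=False
    )
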