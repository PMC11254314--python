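"""Reading, validating and writing differential-entity tables and phenotype series.

The pipeline consumes pre-computed differential calls (one row per entity per
treatment group, with an up/down direction); calling differential expression
from raw counts or spectra is upstream of this package. Identifier
normalisation is deliberately minimal: gene/protein symbols are stored as
given and compared case-insensitively, metabolite names are lowercased with
internal whitespace collapsed, and no synonym resolution is attempted —
matching is by name only.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import FormatError, InputError, ValidationError
from .groups import GroupKey, _fmt_num

log = logging.getLogger(__name__)

ENTITY_KINDS = ("gene", "protein", "metabolite")

#: accepted direction spellings -> canonical label
DIRECTION_TOKENS = {
    "up": "up",
    "down": "down",
    "↑": "up",
    "↓": "down",
    "+1": "up",
    "-1": "down",
}

_WS = re.compile(r"\s+")


def normalize_id(entity_id: str, kind: str) -> str:
    """Canonical comparison key for an identifier.

    Genes/proteins: case-folded (Rrm2 and RRM2 collide on purpose).
    Metabolites: lowercased with runs of whitespace collapsed to one space.
    """
    s = entity_id.strip()
    if not s:
        raise ValidationError("empty entity id after stripping whitespace")
    if kind == "metabolite":
        return _WS.sub(" ", s.lower())
    return s.casefold()


def parse_direction(token: str) -> str:
    t = str(token).strip()
    canonical = DIRECTION_TOKENS.get(t) or DIRECTION_TOKENS.get(t.lower())
    if canonical is None:
        raise ValidationError(f"unknown direction token {token!r}; accepted: {sorted(set(DIRECTION_TOKENS))}")
    return canonical


@dataclass(frozen=True)
class DifferentialRecord:
    """One differential call: an entity moved up or down in one treatment group."""

    entity_id: str
    entity_kind: str
    group: GroupKey
    direction: str
    magnitude: Optional[float] = None
    significance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.entity_kind not in ENTITY_KINDS:
            raise ValidationError(f"entity_kind must be one of {ENTITY_KINDS}, got {self.entity_kind!r}")
        if self.direction not in ("up", "down"):
            raise ValidationError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if self.significance is not None and not (0.0 <= self.significance <= 1.0):
            raise ValidationError(f"significance must lie in [0, 1], got {self.significance}")
        object.__setattr__(self, "entity_id", self.entity_id.strip())
        if not self.entity_id:
            raise ValidationError("empty entity id")

    @property
    def key(self) -> str:
        return normalize_id(self.entity_id, self.entity_kind)


@dataclass
class DifferentialTable:
    """All differential calls of one entity kind, validated and deduplicated."""

    kind: str
    records: tuple[DifferentialRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = [r for r in self.records if r.entity_kind != self.kind]
        if bad:
            raise ValidationError(f"table of kind {self.kind!r} contains records of other kinds: {bad[:3]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def groups(self) -> list[GroupKey]:
        return sorted({r.group for r in self.records})

    def ids_in_group(self, group: GroupKey) -> set[str]:
        """Deduplicated normalized ids called differential in `group`."""
        return {r.key for r in self.records if r.group == group}

    def records_in_group(self, group: GroupKey) -> list[DifferentialRecord]:
        return [r for r in self.records if r.group == group]

    def direction_of(self, key: str, group: GroupKey) -> Optional[str]:
        for r in self.records:
            if r.group == group and r.key == key:
                return r.direction
        return None

    def display_id(self, key: str) -> str:
        """The as-given spelling of a normalized id (first occurrence wins)."""
        for r in self.records:
            if r.key == key:
                return r.entity_id
        return key


def build_table(kind: str, records: Iterable[DifferentialRecord]) -> DifferentialTable:
    """Validate and deduplicate records into a table.

    Duplicate (id, group) rows with the same direction collapse to one,
    keeping the record with the largest |magnitude|; conflicting directions
    for the same (id, group) are a validation error.
    """
    chosen: dict[tuple[str, GroupKey], DifferentialRecord] = {}
    conflicts: list[str] = []
    for rec in records:
        k = (rec.key, rec.group)
        prev = chosen.get(k)
        if prev is None:
            chosen[k] = rec
        elif prev.direction != rec.direction:
            conflicts.append(f"{rec.entity_id} in {rec.group}: {prev.direction} vs {rec.direction}")
        else:
            pm = abs(prev.magnitude) if prev.magnitude is not None else -math.inf
            rm = abs(rec.magnitude) if rec.magnitude is not None else -math.inf
            if rm > pm:
                chosen[k] = rec
    if conflicts:
        raise ValidationError("conflicting directions for: " + "; ".join(sorted(conflicts)))
    ordered = sorted(chosen.values(), key=lambda r: (r.group, r.key))
    return DifferentialTable(kind=kind, records=tuple(ordered))


_REQUIRED_COLS = ("id", "dose_uM", "time_h", "direction")


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_differential_table(path, kind: str) -> DifferentialTable:
    """Read a differential-entity TSV into a validated table.

    Layout: ``id<TAB>kind<TAB>dose_uM<TAB>time_h<TAB>direction[<TAB>magnitude][<TAB>pvalue]``
    with ``#`` comment lines. The ``kind`` column, when present, must agree
    with the requested kind.
    """
    if kind not in ENTITY_KINDS:
        raise ValidationError(f"kind must be one of {ENTITY_KINDS}, got {kind!r}")
    df = _read_tsv(path)
    if df.empty and df.columns.empty:
        log.warning("differential table %s is empty", path)
        return DifferentialTable(kind=kind)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    recs = []
    for _, row in df.iterrows():
        if "kind" in df.columns and str(row["kind"]).strip() != kind:
            raise ValidationError(f"{path}: row {row['id']!r} has kind {row['kind']!r}, expected {kind!r}")
        mag = row.get("magnitude")
        sig = row.get("pvalue")
        recs.append(
            DifferentialRecord(
                entity_id=str(row["id"]),
                entity_kind=kind,
                group=GroupKey(float(row["dose_uM"]), float(row["time_h"])),
                direction=parse_direction(row["direction"]),
                magnitude=float(mag) if mag is not None and not pd.isna(mag) else None,
                significance=float(sig) if sig is not None and not pd.isna(sig) else None,
            )
        )
    return build_table(kind, recs)


def write_differential_table(table: DifferentialTable, path) -> None:
    rows = []
    for r in table.records:
        rows.append(
            {
                "id": r.entity_id,
                "kind": r.entity_kind,
                "dose_uM": _fmt_num(r.group.dose),
                "time_h": _fmt_num(r.group.time),
                "direction": r.direction,
                "magnitude": "" if r.magnitude is None else repr(r.magnitude),
                "pvalue": "" if r.significance is None else repr(r.significance),
            }
        )
    pd.DataFrame(rows, columns=["id", "kind", "dose_uM", "time_h", "direction", "magnitude", "pvalue"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class PhenotypeSeries:
    """Per-group phenotype values (% cell proliferation relative to control)."""

    values: dict[GroupKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, v in self.values.items():
            if not (0.0 < v <= 100.0):
                raise ValidationError(f"phenotype value for {g} must lie in (0, 100], got {v}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def groups(self) -> list[GroupKey]:
        return sorted(self.values)

    def doses(self) -> list[float]:
        return sorted({g.dose for g in self.values})

    def at_dose(self, dose: float) -> list[tuple[GroupKey, float]]:
        return [(g, self.values[g]) for g in self.groups if g.dose == float(dose)]


def read_phenotype_series(path) -> PhenotypeSeries:
    """Read a phenotype TSV (``dose_uM<TAB>time_h<TAB>value``), one row per group."""
    df = _read_tsv(path)
    if df.empty:
        log.warning("phenotype file %s is empty", path)
        return PhenotypeSeries()
    missing = [c for c in ("dose_uM", "time_h", "value") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    values: dict[GroupKey, float] = {}
    for _, row in df.iterrows():
        g = GroupKey(float(row["dose_uM"]), float(row["time_h"]))
        if g in values:
            raise ValidationError(f"{path}: duplicate phenotype row for group {g}")
        values[g] = float(row["value"])
    return PhenotypeSeries(values)


def write_phenotype_series(series: PhenotypeSeries, path) -> None:
    rows = [
        {"dose_uM": _fmt_num(g.dose), "time_h": _fmt_num(g.time), "value": series.values[g]}
        for g in series.groups
    ]
    pd.DataFrame(rows, columns=["dose_uM", "time_h", "value"]).to_csv(path, sep="\t", index=False)
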