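"""Correlation of per-group integration summaries with a phenotype series.

Within each dose, the time-course of cell proliferation is correlated
(product-moment / Pearson) with three per-group indicators: the number of
differential metabolites, of jointly involved pathways, and of pathways with
upstream–downstream relations. A correlation is classified *strong* when the
signed coefficient exceeds the threshold (default r > 0.8); an absolute-value
mode is available for callers who care about association regardless of sign.

With three time points per dose, r carries no meaningful p-value, so none is
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .omics_io import PhenotypeSeries
from .joint_mapping import GroupSummary

INDICATORS = ("differential_metabolites", "joint_pathways", "relation_pathways")

_CLAMP_TOL = 1e-12


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation: cov(x, y) / (sd(x) * sd(y)).

    Raises on unequal lengths, fewer than two points, or a constant sequence
    (zero variance leaves the coefficient undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or xa.size != ya.size:
        raise ValidationError(f"sequences must be 1-d and equal length, got {xa.shape} vs {ya.shape}")
    if xa.size < 2:
        raise ValidationError("need at least two points")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sx = math.sqrt(float(dx @ dx))
    sy = math.sqrt(float(dy @ dy))
    if sx == 0.0:
        raise ValidationError(f"x is constant ({xa[0]!r}); correlation undefined")
    if sy == 0.0:
        raise ValidationError(f"y is constant ({ya[0]!r}); correlation undefined")
    r = float(dx @ dy) / (sx * sy)
    if abs(r) > 1.0:
        if abs(r) - 1.0 > _CLAMP_TOL:
            raise ValidationError(f"pearson_r produced |r| > 1 beyond tolerance: {r}")
        r = math.copysign(1.0, r)
    return r


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson R between the phenotype and one indicator within one dose."""

    dose: float
    indicator: str
    r: float
    n: int
    strong: bool


def correlate_dose(
    phenotype: PhenotypeSeries,
    summaries: Sequence[GroupSummary],
    dose: float,
    threshold: float = 0.8,
    absolute: bool = False,
) -> list[CorrelationReport]:
    """Three correlation reports (one per indicator) for one dose's time-course."""
    pheno_pts = phenotype.at_dose(dose)
    if len(pheno_pts) < 3:
        raise ValidationError(f"need >= 3 time points at dose {dose}, found {len(pheno_pts)}")
    by_group = {s.group: s for s in summaries}
    missing = [str(g) for g, _ in pheno_pts if g not in by_group]
    if missing:
        raise ValidationError(f"summaries missing for group(s): {', '.join(missing)}")
    x = [v for _, v in pheno_pts]
    series = {
        "differential_metabolites": [by_group[g].n_differential_metabolites for g, _ in pheno_pts],
        "joint_pathways": [by_group[g].n_joint_pathways for g, _ in pheno_pts],
        "relation_pathways": [by_group[g].n_relation_pathways for g, _ in pheno_pts],
    }
    out = []
    for ind in INDICATORS:
        r = pearson_r(x, series[ind])
        score = abs(r) if absolute else r
        out.append(CorrelationReport(dose=float(dose), indicator=ind, r=r, n=len(x), strong=score > threshold))
    return out


def correlation_table(reports: Sequence[CorrelationReport]) -> pd.DataFrame:
    """Flat report (r rounded to 3 decimals) ready for TSV/JSON output."""
    return pd.DataFrame(
        [
            {"dose_uM": rep.dose, "indicator": rep.indicator, "r": round(rep.r, 3), "n": rep.n, "strong": rep.strong}
            for rep in reports
        ],
        columns=["dose_uM", "indicator", "r", "n", "strong"],
    )
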