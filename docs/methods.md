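# Methods

## Scope and model

`triomic` integrates *pre-computed* differential calls. Everything upstream
— differential-expression calling from raw counts or spectra, significance
thresholds, vendor formats — is out of scope; the inputs are per-group lists
of (entity, direction) calls, the level at which published differential
tables are reported. Magnitude and p-value columns are accepted and carried
through, but no screening step uses them: pair consistency and relation
detection depend only on direction and group membership.

### Identifier matching

Matching is by name only, with deliberately minimal normalisation: gene and
protein symbols are stored as given and compared case-folded (so the mouse
convention *Rrm2*/RRM2 pairs without a mapping file), and metabolite names
are lowercased with internal whitespace collapsed. No synonym or compound-ID
resolution is attempted; a knowledge base must therefore use the same
nomenclature as the metabolite tables. An explicit one-to-one gene→protein
mapping file overrides the case-insensitive default when identifiers do not
follow that convention.

### Upstream–downstream semantics

A pathway is modelled as a simple directed graph over its member
metabolites; each edge is one reaction step annotated with the genes
encoding its catalysts. Gene *g* is upstream of metabolite *m* when a
directed path of length ≤ `max_hops` exists whose **first** edge is
catalysed by *g* and which ends at *m*. Choices embedded here:

- **Multi-hop by default** (`max_hops = None`). An enzyme several steps
  above a metabolite still controls its pool; restricting to immediate
  products would miss, e.g., a reductase acting four steps above a terminal
  catabolite. `--max-hops` tightens this when adjacency is wanted.
- **Reversibility lives in the data.** A reversible reaction is encoded as
  two opposed edges; the query code treats all edges as directed. The
  continuation of a path may therefore revisit the first edge's source —
  only the continuation from the first edge's target is required to be
  simple, and hop counts are shortest-path lengths from that target plus
  one (computed by breadth-first search; the tests check it against
  exhaustive path enumeration).
- **Membership gates reachability.** A gene absent from a pathway's member
  set has an empty downstream set even if an identically named catalyst
  appears on an edge; pathway co-occurrence likewise requires the *gene*
  member — protein membership is implied by the gene, and the KB stores
  genes only.

### Network decomposition and ranking

Relation links induce an undirected tripartite graph (pair, metabolite and
pathway nodes; edges only between types). The same entity observed in
several groups is one node — the biomarker question is group-agnostic — with
group provenance kept as node metadata. Components are ranked by
(n_metabolites desc, n_pathways desc, n_pairs desc), metabolites first
because the candidate panel is selected for metabolite coverage, with the
lexicographically smallest gene key as a final deterministic tie-break (the
published source states no tie-break; this chain is this package's choice).
Candidates are the pairs and metabolites of the top component; an empty
network yields an explicit empty candidate set rather than an error.

### Correlation

Pearson's product-moment coefficient is implemented directly from the
closed form and cross-checked against `scipy.stats.pearsonr` in the tests.
The *strong* classification applies the threshold (default 0.8) to the
**signed** r, matching the convention of reporting "R > 0.8"; an
absolute-value mode (`--abs-r`) exists because anticorrelation can be
equally informative. With three time points per dose no meaningful p-value
exists and none is reported. Constant indicator series raise an explicit
error naming the offending sequence; |r| is clamped to 1 within 1e-12.

## Bundled fixtures

The worked-example fixtures transcribe a published Ni²⁺/L929 cytotoxicity
study's screened entities: 8 gene and 8 protein differential calls forming
6 distinct consistent pairs, 13 differential metabolites over four of the
six 2 dose x 3 time groups, the six-point proliferation series, and the
published per-group indicator counts used as correlation inputs. The mini
pathway knowledge base is hand-curated at coarse granularity: ten pathways
(seven signal, three decoys containing none of the signal genes) whose
reaction chains realise every published upstream–downstream relation —
e.g. GDP -[Rrm2]→ dGDP → dGMP → … → uric acid. Two steps are coarser than
the reference maps (UDP-GlcNAc → glucose 1-phosphate collapses the
nucleotide-sugar interconversion; uracil → uridine encodes the forward
direction of the reversible phosphorylase step) so that every relation is
realisable in a small graph. It is a test fixture, not a KEGG mirror;
currency metabolites (ATP, H₂O, …) are excluded to avoid trivial shortcut
paths. Because the fixture tables contain only the relation-bearing
entities (the study's full supplementary lists are not publicly deposited),
fixture-derived joint-pathway counts coincide with relation-pathway counts;
the published joint counts are therefore shipped as data
(`printed_group_counts.tsv`) and used as the correlation inputs, which is
also what the original analysis correlated.

## Synthetic generator

`synthetic.simulate_kb` emits pathways as directed metabolite chains
(default 8 pathways, chain length 4–8, 25% of steps uncatalysed, an
optional branch per pathway) — the same shape as the fixture KB, scaled for
property testing. `simulate_tables` plants direction-consistent pairs
(default 4) and relations (default 6) over the default 2 dose x 3 time
design, then adds noise calls at each layer (default 8 per layer). The
defaults mirror the study's scale: a handful of relation-bearing pairs
against a larger differential background.

Exactness of the ground truth is the design priority:

- Pair/relation draws whose genes run out of distinct downstream
  metabolites are rejected and redrawn (≤ 50 attempts, then a configuration
  error) — the generator never emits an instance whose truth it cannot
  realise.
- The truth is **closed under reachability**: when two planted pairs share
  a pathway and group, each gene's relations to the other's metabolite are
  recorded too, since they are equally real in the emitted data.
- Noise cannot fabricate signal: noise genes and proteins use disjoint
  namespaces outside the KB (so no accidental consistent pair), and noise
  metabolites are drawn only from KB metabolites not downstream of any
  planted gene (an exact filter; an empty pool is a configuration error).
- `p_direction_flip` breaks planted pairs' gene/protein concordance; a
  flipped pair and its relations leave the truth entirely.

`evaluate_recovery` scores precision/recall on three layers — pairs,
relation links, subnetwork node-sets (computed truth-side by an independent
union-find, not by the pipeline's decomposition). An empty prediction
scores precision 1.0 by convention, with a warning.

What the generator does **not** emulate: raw intensity distributions,
realistic KEGG-scale topology (hubs, currency metabolites), correlated
noise across omics layers, or name ambiguity. Perfect synthetic recovery
therefore demonstrates the correctness of the integration logic, not
robustness to the noise structure of real multi-omics data.

## Numerical and procedural choices

- All orderings are total and documented (records by (group, key); hits by
  (|relations| desc, pathway id); catalogue by (dose, time, pathway, gene,
  metabolite); components as above), so reruns are byte-identical except
  the run log's timestamp.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; the KB and the tables use separate streams
  (seed, seed + 1) so enlarging one plant count does not reshuffle the
  other draw.
- Degenerate inputs are defined, not accidental: empty tables are valid
  (empty result bundle, exit 0 with a warning); contradictory directions
  for one entity in one group are a validation error listing the
  offenders; duplicate identical calls collapse keeping the largest
  |magnitude|.
- CLI exit codes separate validation (2), I/O (3) and configuration (4)
  failures.

## Problem sizes

The bundled worked example is desk-scale (26 network nodes, 13 relation
links) and each stage completes in well under a second. Property tests use
graphs of ≤ 12 metabolites x 250 cases (reachability vs exhaustive
enumeration), networks of ≤ 23 nodes x 150 cases (decomposition vs label
propagation), tables of ≤ 50 entities (screen vs double loop), and 20-seed
recovery runs
of the default synthetic configuration — sizes at which the brute-force
oracles are exact and the whole suite stays fast.

## Known limitations

- Name-based matching makes the pipeline only as good as the nomenclature
  agreement between tables and KB; no compound-ID resolution is attempted.
- The gene→protein map is one-to-one; isoforms and many-to-many products
  are out of scope.
- Joint mapping is plain co-membership: no over-representation statistics
  or topology-impact scores are computed.
- Three points per dose make the correlation stage descriptive, not
  inferential.
- The relation definition ignores edge direction *consistency* (an ↑ gene
  above an ↓ metabolite still links); directionality of effects is retained
  in the catalogue for the reader but not filtered on.
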