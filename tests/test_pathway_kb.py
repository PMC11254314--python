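"""Pathway KB loading and upstream-downstream reachability vs a DFS path oracle."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from triomic.errors import ValidationError
from triomic.pathway_kb import (
    Pathway,
    PathwayKB,
    ReactionEdge,
    downstream_metabolites,
    downstream_with_hops,
    has_upstream_downstream,
    load_kb,
)

SIGNAL_PATHWAYS = {"purine", "pyrimidine", "ufa", "cysmet", "aminosugar", "porphyrin", "glycerophospholipid"}


class TestLoadKB:
    def test_fixture_kb_composition(self, fixture_kb):
        assert len(fixture_kb) >= 10
        assert SIGNAL_PATHWAYS <= set(fixture_kb.pathways)
        # decoys contain none of the signal genes
        signal_genes = {"rrm2", "acot2", "mat2a", "gnpnat1", "cp", "gpd1"}
        for pid in set(fixture_kb.pathways) - SIGNAL_PATHWAYS:
            assert fixture_kb.pathways[pid].member_genes.isdisjoint(signal_genes)

    def test_empty_files_give_empty_kb(self, tmp_path):
        (tmp_path / "m.tsv").write_text("")
        (tmp_path / "e.tsv").write_text("")
        kb = load_kb(tmp_path / "m.tsv", tmp_path / "e.tsv")
        assert len(kb) == 0

    def test_edge_citing_unknown_pathway_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("pw1\tPathway one\tm:a\tm:b\n")
        (tmp_path / "e.tsv").write_text("X\ta\tb\t\n")
        with pytest.raises(ValidationError, match="unknown pathway"):
            load_kb(tmp_path / "m.tsv", tmp_path / "e.tsv")

    def test_edge_to_nonmember_metabolite_rejected(self, tmp_path):
        (tmp_path / "m.tsv").write_text("pw1\tPathway one\tm:a\n")
        (tmp_path / "e.tsv").write_text("pw1\ta\tzz\t\n")
        with pytest.raises(ValidationError, match="not a member"):
            load_kb(tmp_path / "m.tsv", tmp_path / "e.tsv")

    def test_parallel_edges_merge_catalysts(self):
        pw = Pathway("p", "p", member_genes={"g1", "g2"}, member_metabolites={"a", "b"})
        kb = PathwayKB([pw], [
            ReactionEdge("p", "a", "b", frozenset({"g1"})),
            ReactionEdge("p", "a", "b", frozenset({"g2"})),
        ])
        assert kb.graph("p")["a"]["b"]["catalysts"] == {"g1", "g2"}


class TestFixtureReachability:
    def test_rrm2_reaches_uric_acid_and_dgmp_in_purine(self, fixture_kb):
        down = downstream_metabolites(fixture_kb, "purine", "Rrm2")
        assert {"uric acid", "dgmp"} <= down

    def test_rrm2_upstream_of_uridine_in_pyrimidine(self, fixture_kb):
        assert has_upstream_downstream(fixture_kb, "pyrimidine", "Rrm2", "Uridine")
        assert has_upstream_downstream(fixture_kb, "pyrimidine", "Rrm2", "dUMP")

    def test_nonmember_gene_has_empty_downstream(self, fixture_kb):
        assert downstream_metabolites(fixture_kb, "purine", "Gpd1") == set()
        assert not has_upstream_downstream(fixture_kb, "purine", "Gpd1", "uric acid")

    def test_unknown_pathway_raises(self, fixture_kb):
        with pytest.raises(ValidationError):
            downstream_metabolites(fixture_kb, "no-such-map", "Rrm2")

    def test_hop_bound_truncates_reach(self, fixture_kb):
        assert downstream_with_hops(fixture_kb, "purine", "Rrm2", max_hops=2) == {"dgdp": 1, "dgmp": 2}


# --- random-graph oracle ---------------------------------------------------

def dfs_oracle(edges, gene, max_hops=None):
    """Brute force: enumerate every simple continuation from each catalysed first edge.

    The first edge's own source may be revisited downstream (opposed-edge
    pairs encode reversible reactions), so only the continuation from the
    first edge's target must be simple.
    """
    out = {}
    firsts = [(u, v) for u, v, cats in edges if gene in cats]
    adj = {}
    for u, v, _ in edges:
        adj.setdefault(u, set()).add(v)

    def walk(node, depth, seen):
        for nxt in adj.get(node, ()):
            if nxt in seen:
                continue
            d = depth + 1
            if max_hops is not None and d > max_hops:
                continue
            if nxt not in out or out[nxt] > d:
                out[nxt] = d
            walk(nxt, d, seen | {nxt})

    for _, v in firsts:
        if v not in out or out[v] > 1:
            out[v] = 1
        walk(v, 1, {v})
    return out


def _mk_kb(edges, genes):
    mets = {u for u, _, _ in edges} | {v for _, v, _ in edges}
    pw = Pathway("p", "p", member_genes=set(genes), member_metabolites=mets)
    return PathwayKB([pw], [ReactionEdge("p", u, v, frozenset(c)) for u, v, c in edges])


edge_lists = st.lists(
    st.tuples(st.sampled_from([f"m{i}" for i in range(12)]),
              st.sampled_from([f"m{i}" for i in range(12)]),
              st.frozensets(st.sampled_from(["g0", "g1"]), max_size=2)),
    min_size=1, max_size=24,
).map(lambda es: [(u, v, c) for u, v, c in es if u != v])


@settings(max_examples=250, derandomize=True)
@given(edge_lists, st.sampled_from(["g0", "g1"]), st.one_of(st.none(), st.integers(1, 6)))
def test_reachability_equals_dfs_path_oracle(edges, gene, max_hops):
    """BFS reachability agrees with exhaustive simple-path enumeration.

    The shortest qualifying walk never needs to revisit a node, so simple-path
    enumeration is a valid oracle for both membership and hop counts.
    """
    seen = set()
    dedup = [e for e in edges if (e[0], e[1]) not in seen and not seen.add((e[0], e[1]))]
    if not dedup:
        return
    kb = _mk_kb(dedup, ["g0", "g1"])
    got = downstream_with_hops(kb, "p", gene, max_hops=max_hops)
    assert got == dfs_oracle(dedup, gene, max_hops)


@settings(max_examples=100, derandomize=True)
@given(edge_lists, st.integers(1, 5))
def test_downstream_monotone_in_max_hops(edges, k):
    if not edges:
        return
    kb = _mk_kb(edges, ["g0", "g1"])
    at_k = downstream_metabolites(kb, "p", "g0", max_hops=k)
    at_k1 = downstream_metabolites(kb, "p", "g0", max_hops=k + 1)
    unbounded = downstream_metabolites(kb, "p", "g0")
    assert at_k <= at_k1 <= unbounded


@settings(max_examples=60, derandomize=True)
@given(edge_lists)
def test_result_invariant_under_edge_permutation(edges):
    if not edges:
        return
    for perm in itertools.islice(itertools.permutations(edges), 3):
        assert downstream_with_hops(_mk_kb(list(perm), ["g0"]), "p", "g0") == \
            downstream_with_hops(_mk_kb(edges, ["g0"]), "p", "g0")
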