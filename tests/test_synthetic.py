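"""Synthetic instance generation: determinism, soundness, and exact recovery."""

import pytest

from triomic.errors import ConfigError
from triomic.omics_io import read_differential_table, write_differential_table
from triomic.pathway_kb import has_upstream_downstream, load_kb, write_kb
from triomic.pair_screen import pair_counts_by_group
from triomic.pipeline import run_integration
from triomic.synthetic import (
    GroundTruth,
    LayerScore,
    SimulationConfig,
    evaluate_recovery,
    simulate_kb,
    simulate_tables,
)


def _noise_free(seed):
    return SimulationConfig(seed=seed, noise_genes=0, noise_proteins=0, noise_metabolites=0)


class TestSimulateKB:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=1, n_pathways=5)
        kb1, kb2 = simulate_kb(cfg), simulate_kb(cfg)
        assert sorted(kb1.pathways) == sorted(kb2.pathways)
        for pid in kb1.pathways:
            assert sorted(kb1.graph(pid).edges(data=True)) == sorted(kb2.graph(pid).edges(data=True))

    def test_zero_pathways_gives_empty_kb(self):
        assert len(simulate_kb(SimulationConfig(seed=0, n_pathways=0))) == 0

    def test_degenerate_chain_length_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(seed=0, chain_length_range=(1, 3))

    def test_roundtrip_through_file_formats_revalidates(self, tmp_path):
        kb = simulate_kb(SimulationConfig(seed=4))
        write_kb(kb, tmp_path / "m.tsv", tmp_path / "e.tsv")
        back = load_kb(tmp_path / "m.tsv", tmp_path / "e.tsv")
        assert sorted(back.pathways) == sorted(kb.pathways)
        for pid in kb.pathways:
            assert sorted(back.graph(pid).edges(data=True)) == sorted(kb.graph(pid).edges(data=True))
            assert back.pathways[pid].member_genes == kb.pathways[pid].member_genes


class TestSimulateTables:
    def test_byte_identical_tables_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(seed=11)
        kb = simulate_kb(cfg)
        for run in (1, 2):
            genes, _, mets, _ = simulate_tables(cfg, kb)
            write_differential_table(genes, tmp_path / f"g{run}.tsv")
            write_differential_table(mets, tmp_path / f"m{run}.tsv")
        assert (tmp_path / "g1.tsv").read_bytes() == (tmp_path / "g2.tsv").read_bytes()
        assert (tmp_path / "m1.tsv").read_bytes() == (tmp_path / "m2.tsv").read_bytes()

    def test_planted_relations_are_sound(self):
        """Every truth relation is confirmed by reachability on the emitted KB."""
        cfg = SimulationConfig(seed=2)
        kb = simulate_kb(cfg)
        _, _, _, truth = simulate_tables(cfg, kb)
        assert truth.relations
        for rel in truth.relations:
            assert has_upstream_downstream(kb, rel.pathway_id, rel.pair.gene_id, rel.metabolite_id)

    def test_full_direction_flip_erases_all_pairs(self):
        cfg = SimulationConfig(seed=3, p_direction_flip=1.0,
                               noise_genes=0, noise_proteins=0, noise_metabolites=0)
        kb = simulate_kb(cfg)
        genes, prots, _, truth = simulate_tables(cfg, kb)
        assert sum(pair_counts_by_group(genes, prots).values()) == 0
        assert truth.pairs == set() and truth.relations == set()

    def test_infeasible_plant_count_raises(self):
        cfg = SimulationConfig(seed=0, n_pathways=1, chain_length_range=(2, 2),
                               n_planted_pairs=1, n_planted_relations=50)
        kb = simulate_kb(cfg)
        with pytest.raises(ConfigError, match="relations"):
            simulate_tables(cfg, kb)


class TestRecovery:
    @pytest.mark.parametrize("seed", range(22))
    def test_noise_free_recovery_is_perfect(self, seed):
        """Precision = recall = 1.0 on all three layers without noise or flips."""
        cfg = _noise_free(seed)
        kb = simulate_kb(cfg)
        genes, prots, mets, truth = simulate_tables(cfg, kb)
        rep = evaluate_recovery(run_integration(genes, prots, mets, kb), truth)
        for layer in (rep.pairs, rep.relations, rep.subnetworks):
            assert layer == LayerScore(precision=1.0, recall=1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_noise_never_hides_planted_signal(self, seed):
        """With noise entities present, recall stays 1.0 and no spurious relation appears."""
        cfg = SimulationConfig(seed=seed)
        kb = simulate_kb(cfg)
        genes, prots, mets, truth = simulate_tables(cfg, kb)
        rep = evaluate_recovery(run_integration(genes, prots, mets, kb), truth)
        assert rep.pairs.recall == 1.0
        assert rep.relations == LayerScore(precision=1.0, recall=1.0)

    def test_empty_output_scores_vacuous_precision(self):
        truth = GroundTruth()
        truth.pairs = {"x"}

        class Empty:
            pairs, relations, subnetworks = (), (), ()

        rep = evaluate_recovery(Empty(), truth)
        assert rep.pairs == LayerScore(precision=1.0, recall=0.0)

    def test_spurious_prediction_arithmetic(self):
        truth = GroundTruth()
        truth.relations = {"r1", "r2"}

        class Out:
            pairs, subnetworks = (), ()
            relations = ("r1", "r2", "bogus")

        rep = evaluate_recovery(Out(), truth)
        assert rep.relations.precision == pytest.approx(2 / 3)
        assert rep.relations.recall == 1.0
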