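"""The synthetic population generator and its ground-truth guarantees."""

import math

import numpy as np
import pytest

from csdpop import synthetic
from csdpop.novelty import classify_novelty
from csdpop.richness import occupancy_mean, occupancy_var, queen_detection_prob
from csdpop.synthetic import (
    SimConfig,
    make_allele_pool,
    maternal_observations,
    simulate_population,
    snapshot_reference,
)


class TestMakeAllelePool:
    def test_degenerate_config_is_deterministic(self):
        cfg = SimConfig(
            n_alleles=2, hvr_len_range=(4, 5), hvr_subst_rate=0.0, seed=1
        )
        # with no substitutions the HVR is a pure repeat of the unit
        pool, _ = make_allele_pool(cfg)
        for rec in pool:
            assert rec.hvr_seq == "NY" * (rec.hvr_len // 2)
            assert rec.aa_seq == cfg.flank_left + rec.hvr_seq + cfg.flank_right

    def test_pool_is_distinct_with_correct_spans(self):
        cfg = SimConfig(n_alleles=50, hvr_len_range=(5, 25), seed=3)
        pool, truth = make_allele_pool(cfg)
        seqs = [r.aa_seq for r in pool]
        assert len(set(seqs)) == 50
        for rec in pool:
            s, e = rec.hvr_span
            assert s == len(cfg.flank_left)
            assert len(rec.aa_seq) - e == len(cfg.flank_right)
        assert math.isclose(sum(t.frequency for t in truth.alleles.values()), 1.0)

    def test_impossible_range_errors(self):
        cfg = SimConfig(
            n_alleles=10, hvr_len_range=(1, 1), hvr_subst_rate=0.0, seed=0
        )
        with pytest.raises(ValueError, match="widen"):
            make_allele_pool(cfg)

    def test_frequency_models(self, rng):
        geo = SimConfig(n_alleles=10, freq_model="geometric", freq_param=0.5, seed=2)
        _, truth = make_allele_pool(geo, rng)
        freqs = [t.frequency for t in truth.alleles.values()]
        assert freqs == sorted(freqs, reverse=True)
        assert math.isclose(sum(freqs), 1.0)


class TestSimulatePopulation:
    def simulate(self, cfg):
        rng = np.random.default_rng(cfg.seed)
        pool, truth = make_allele_pool(cfg, rng)
        return simulate_population(cfg, pool, truth, rng)

    def test_drone_counts_exact(self):
        cfg = SimConfig(n_alleles=20, n_apiaries=3, colonies_per_apiary=4, seed=9)
        drones, _, truth = self.simulate(cfg)
        assert len(drones) == 3 * 4 * cfg.drones_per_colony
        per_colony = drones.groupby("colony_id").size()
        assert (per_colony == cfg.drones_per_colony).all()
        assert len(truth.queens) == 12

    def test_queens_heterozygous(self):
        cfg = SimConfig(n_alleles=10, n_apiaries=4, colonies_per_apiary=10, seed=13)
        _, _, truth = self.simulate(cfg)
        assert all(a != b for a, b in truth.queens.values())

    def test_both_alleles_detected_at_expected_rate(self):
        """With 6 drones per colony both queen alleles surface in about
        1 - 2^-5 = 96.9% of colonies."""
        cfg = SimConfig(
            n_alleles=50,
            n_apiaries=8,
            colonies_per_apiary=50,
            drones_per_colony=6,
            swarm_dup_prob=0.0,
            mutation_prob=0.0,
            seed=21,
        )
        drones, _, truth = self.simulate(cfg)
        obs = maternal_observations(drones)
        both = (obs.groupby("colony_id").size() == 2).sum()
        n = len(truth.queens)
        p = queen_detection_prob(6)
        assert abs(both / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_distinct_count_consistent_with_occupancy_chain(self):
        """Without swarm duplication or mutation, the number of distinct
        alleles among the queen draws matches the occupancy model."""
        cfg = SimConfig(
            n_alleles=100,
            n_apiaries=5,
            colonies_per_apiary=6,
            swarm_dup_prob=0.0,
            mutation_prob=0.0,
            seed=31,
        )
        reps, distinct = 60, []
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            pool, truth = make_allele_pool(cfg, rng)
            _, _, t = simulate_population(cfg, pool, truth, rng)
            alleles = [a for pair in t.queens.values() for a in pair]
            distinct.append(len(set(alleles)))
        D = 2 * cfg.n_apiaries * cfg.colonies_per_apiary
        mean = occupancy_mean(cfg.n_alleles, D)
        tol = 3 * math.sqrt(occupancy_var(cfg.n_alleles, D) / reps) + 0.25
        # +0.25 slack: queen pairs are drawn distinct, a slight upward push
        assert abs(np.mean(distinct) - mean) < tol

    def test_mutants_are_novel_and_marked(self):
        cfg = SimConfig(
            n_alleles=30, n_apiaries=6, colonies_per_apiary=10,
            mutation_prob=0.3, seed=37,
        )
        rng = np.random.default_rng(cfg.seed)
        pool, truth = make_allele_pool(cfg, rng)
        _, records, truth = simulate_population(cfg, pool, truth, rng)
        mutants = truth.mutant_ids()
        assert mutants  # at this rate some mutation happened
        base_seqs = {r.aa_seq for r in pool}
        by_id = {r.id: r for r in records}
        for m in mutants:
            assert by_id[m].aa_seq not in base_seqs
        # all sequences in the extended pool remain pairwise distinct
        assert len({r.aa_seq for r in records}) == len(records)

    def test_inputs_not_modified(self):
        cfg = SimConfig(n_alleles=10, n_apiaries=2, colonies_per_apiary=3,
                        mutation_prob=0.5, seed=41)
        rng = np.random.default_rng(cfg.seed)
        pool, truth = make_allele_pool(cfg, rng)
        n_pool, n_truth = len(pool), len(truth.alleles)
        simulate_population(cfg, pool, truth, rng)
        assert len(pool) == n_pool and len(truth.alleles) == n_truth


class TestSnapshotReference:
    def setup_sim(self):
        cfg = SimConfig(n_alleles=25, n_apiaries=4, colonies_per_apiary=6,
                        mutation_prob=0.25, seed=51)
        rng = np.random.default_rng(cfg.seed)
        pool, truth = make_allele_pool(cfg, rng)
        drones, records, truth = simulate_population(cfg, pool, truth, rng)
        return cfg, rng, drones, records, truth

    def test_full_reference_marks_base_alleles_known(self):
        cfg, rng, drones, records, truth = self.setup_sim()
        ref = snapshot_reference(records, truth, 1.0, rng)
        obs = maternal_observations(drones)
        seen = obs["allele_id"].unique()
        by_id = {r.id: r for r in records}
        n_ap = obs.groupby("allele_id")["apiary_id"].nunique().to_dict()
        table = classify_novelty([by_id[a] for a in seen], ref, n_ap)
        mutants = truth.mutant_ids()
        for row in table.itertuples():
            # mutants post-date the snapshot and are always unique;
            # everything else is covered by the full reference
            assert row.is_unique == (row.allele_id in mutants)

    def test_zero_fraction_everything_unique(self):
        cfg, rng, drones, records, truth = self.setup_sim()
        assert snapshot_reference(records, truth, 0.0, rng) == []

    def test_fraction_validated(self):
        cfg, rng, _, records, truth = self.setup_sim()
        with pytest.raises(ValueError):
            snapshot_reference(records, truth, 1.5, rng)


def test_write_outputs_round_trip(tmp_path):
    """Simulated data can be written and re-read by the sequences stage."""
    from csdpop import sequences

    cfg = SimConfig(n_alleles=15, n_apiaries=2, colonies_per_apiary=4, seed=61)
    rng = np.random.default_rng(cfg.seed)
    pool, truth = make_allele_pool(cfg, rng)
    drones, records, truth = simulate_population(cfg, pool, truth, rng)
    obs = maternal_observations(drones)
    ref = snapshot_reference(records, truth, 0.5, rng)
    paths = synthetic.write_outputs(tmp_path, cfg, records, truth, obs, ref)

    reads = sequences.read_fasta(paths["observations_nt"])
    assert len(reads) == len(obs)
    by_id = {r.id: r for r in records}
    for read, row in zip(reads, obs.itertuples()):
        n_aa = len(read.seq) // 3
        spec = sequences.RegionSpec(
            frame_offset=0, region_start=0, region_end=n_aa,
            hvr_start=len(cfg.flank_left), hvr_end=n_aa - len(cfg.flank_right),
        )
        assert sequences.translate_region(read, spec).aa_seq == by_id[row.allele_id].aa_seq
    sheet = sequences.read_sample_sheet(paths["sample_sheet"])
    assert list(sheet["id"]) == list(obs["obs_id"])
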