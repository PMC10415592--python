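"""Synthetic generators: reproducibility and recorded ground truth."""

import numpy as np
import pytest

from hgtclock.assess import is_compatible
from hgtclock.dtl import CostVector, reconcile
from hgtclock.seqscan import classify_proteome, scan_heme_motifs
from hgtclock.synth import (
    SimConfig,
    jitter_ensemble,
    plant_transfers,
    simulate_bd_tree,
    simulate_dtl_gene_tree,
    synth_proteome,
)
from hgtclock.trees import to_chronogram


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, birth_rate=-1)
        with pytest.raises(ValueError):
            SimConfig(seed=1, jitter_cv=-0.1)
        with pytest.raises(ValueError):
            SimConfig(seed=1, n_samples=0)


class TestBirthDeathTree:
    def test_two_taxa_single_internal_node(self):
        ch = simulate_bd_tree(SimConfig(seed=4, n_taxa=2))
        internal = [n for n in ch.tree.postorder_internal_node_iter()]
        assert len(internal) == 1
        assert internal[0] is ch.root

    def test_pure_birth_structure(self):
        ch = simulate_bd_tree(SimConfig(seed=8, n_taxa=8, death_rate=0.0))
        internal = list(ch.tree.postorder_internal_node_iter())
        assert len(internal) == 7
        for nd in internal:
            for child in nd.child_nodes():
                assert ch.age(nd) > ch.age(child)

    def test_bit_reproducible(self):
        cfg = SimConfig(seed=123, n_taxa=10)
        a = simulate_bd_tree(cfg)
        b = simulate_bd_tree(cfg)
        assert a.as_newick() == b.as_newick()

    def test_root_age_bound_respected(self):
        cfg = SimConfig(seed=9, n_taxa=6, root_age_max=500.0)
        for _ in range(3):
            assert simulate_bd_tree(cfg).root_age <= 500.0

    def test_mean_root_age_matches_independent_reference_simulation(self):
        # pure birth: after the first split, the wait at k lineages is
        # Exp(k*b); the present is placed a uniform fraction into the
        # waiting interval after the n-th lineage arises.  Re-simulating
        # just those sums is an independent implementation of the process.
        n_rep, n_taxa, birth = 1000, 6, 1.0
        cfg = SimConfig(
            seed=202, n_taxa=n_taxa, birth_rate=birth, death_rate=0.0,
            root_age_max=None,
        )
        rng = np.random.default_rng(202)
        ours = np.array(
            [simulate_bd_tree(cfg, rng=rng).root_age for _ in range(n_rep)]
        )
        ref_rng = np.random.default_rng(404)
        waits = np.stack(
            [
                ref_rng.exponential(1.0 / (k * birth), size=n_rep)
                for k in range(2, n_taxa)
            ]
        ).sum(axis=0)
        dwell = ref_rng.exponential(
            1.0 / (n_taxa * birth), size=n_rep
        ) * ref_rng.random(n_rep)
        ref = waits + dwell
        se = np.sqrt(ours.var() / n_rep + ref.var() / n_rep)
        assert abs(ours.mean() - ref.mean()) < 3 * se

    def test_mean_root_age_against_dendropy_cross_check(self):
        # dendropy stops exactly at the n-th birth, so its mean crown age
        # sits one expected half-interval 1/(2*n*b) below ours
        import random

        from dendropy.model import birthdeath

        n_rep, n_taxa, birth = 300, 6, 1.0
        cfg = SimConfig(
            seed=207, n_taxa=n_taxa, birth_rate=birth, death_rate=0.0,
            root_age_max=None,
        )
        rng = np.random.default_rng(207)
        ours = np.array(
            [simulate_bd_tree(cfg, rng=rng).root_age for _ in range(n_rep)]
        )
        ref_rng = random.Random(404)
        ref = []
        for _ in range(n_rep):
            t = birthdeath.birth_death_tree(
                birth, 0.0, num_extant_tips=n_taxa, rng=ref_rng
            )
            t.calc_node_ages(ultrametricity_precision=1e-6)
            ref.append(t.seed_node.age)
        ref = np.array(ref)
        dwell_offset = 1.0 / (2 * n_taxa * birth)
        se = np.sqrt(ours.var() / n_rep + ref.var() / n_rep)
        assert abs(ours.mean() - (ref.mean() + dwell_offset)) < 3 * se


class TestJitterEnsemble:
    def test_zero_cv_identical_to_truth(self):
        cfg = SimConfig(seed=31, n_taxa=6, jitter_cv=0.0, n_samples=5)
        truth = simulate_bd_tree(cfg)
        ens = jitter_ensemble(truth, cfg)
        for ch in ens:
            for nd in truth.tree.postorder_node_iter():
                assert ch.node_age[nd] == pytest.approx(
                    truth.node_age[nd], abs=1e-6 * truth.root_age
                )

    def test_every_sample_validates_as_chronogram(self):
        cfg = SimConfig(seed=32, n_taxa=10, jitter_cv=0.3, n_samples=50)
        truth = simulate_bd_tree(cfg)
        from hgtclock.trees import Chronogram

        for ch in jitter_ensemble(truth, cfg):
            Chronogram.from_newick(ch.as_newick())  # re-parse, re-validate
            for nd in truth.tree.preorder_internal_node_iter():
                assert ch.node_age[nd] > max(
                    ch.node_age[c] for c in nd.child_nodes()
                )

    def test_bit_reproducible(self):
        cfg = SimConfig(seed=33, n_taxa=6, n_samples=10)
        truth = simulate_bd_tree(cfg)
        a = jitter_ensemble(truth, cfg)
        b = jitter_ensemble(truth, cfg)
        for x, y in zip(a, b):
            assert x.node_age == y.node_age

    def test_per_node_mean_within_three_se(self):
        cfg = SimConfig(seed=34, n_taxa=8, jitter_cv=0.05, n_samples=1000)
        truth = simulate_bd_tree(cfg)
        ens = jitter_ensemble(truth, cfg)
        cv = cfg.jitter_cv
        mean_noise = float(np.exp(0.5 * np.log1p(cv * cv)))
        for nd in truth.tree.postorder_internal_node_iter():
            ages = np.array([ch.node_age[nd] for ch in ens])
            expected = truth.node_age[nd] * mean_noise
            se = ages.std(ddof=1) / np.sqrt(len(ages))
            # repair floors push some nodes up; allow the one-sided slack
            assert ages.mean() - expected > -3 * se
            assert ages.mean() - expected < 3 * se + 2e-2 * truth.node_age[nd]


class TestPlantTransfers:
    def test_clades_disjoint_and_intervals_contain_time(self):
        cfg = SimConfig(seed=41, n_taxa=10)
        truth = simulate_bd_tree(cfg)
        for pt in plant_transfers(truth, 5, 7):
            assert not pt.donor_clade & pt.recipient_clade
            for clade in (pt.donor_clade, pt.recipient_clade):
                crown = truth.crown_age(clade)
                stem = truth.stem_age(clade)
                assert crown < pt.time < stem

    def test_stem_crown_constraints_true_on_truth(self):
        cfg = SimConfig(seed=42, n_taxa=10)
        truth = simulate_bd_tree(cfg)
        for pt in plant_transfers(truth, 8, 11):
            assert pt.constraint.mode == "stem-crown"
            assert is_compatible(truth, pt.constraint)

    def test_zero_jitter_matches_truth_relation(self):
        cfg = SimConfig(seed=43, n_taxa=8, jitter_cv=0.0, n_samples=20)
        truth = simulate_bd_tree(cfg)
        ens = jitter_ensemble(truth, cfg)
        for pt in plant_transfers(truth, 4, 13):
            expected = is_compatible(truth, pt.constraint)
            assert all(
                is_compatible(ch, pt.constraint) == expected for ch in ens
            )


class TestDtlGeneSimulation:
    def test_rates_zero_congruent_cost_zero(self):
        cfg = SimConfig(seed=51, n_taxa=7, dtl_rates=(0.0, 0.0, 0.0))
        truth = simulate_bd_tree(cfg)
        gene, events = simulate_dtl_gene_tree(truth, cfg)
        assert gene is not None
        assert len(gene.leaf_nodes()) == cfg.n_taxa
        assert all(ev.kind == "speciation" for ev in events)
        assert reconcile(gene, truth.tree, CostVector(1, 1, 1)).total_cost == 0

    def test_no_loss_conserves_leaf_count(self):
        cfg = SimConfig(seed=52, n_taxa=7, dtl_rates=(0.0, 0.0, 0.0))
        truth = simulate_bd_tree(cfg)
        gene, _ = simulate_dtl_gene_tree(truth, cfg)
        assert len(gene.leaf_nodes()) == len(truth.leaf_labels)

    def test_events_recorded_with_times_inside_tree(self):
        cfg = SimConfig(seed=53, n_taxa=8, dtl_rates=(0.001, 0.002, 0.0005))
        truth = simulate_bd_tree(cfg)
        rng = cfg.rng()
        gene, events = simulate_dtl_gene_tree(truth, cfg, rng=rng)
        for ev in events:
            assert 0 <= ev.time <= truth.root_age
            if ev.kind == "transfer":
                assert ev.recipient_clade is not None
                assert not ev.species_clade & ev.recipient_clade


class TestSynthProteome:
    def test_zero_motif_plan(self):
        recs = synth_proteome(SimConfig(seed=61, motif_plan=((3, 0),)))
        assert len(recs) == 3
        assert all(len(scan_heme_motifs(r.sequence)) == 0 for r in recs)

    def test_planted_two_by_two(self):
        recs = synth_proteome(SimConfig(seed=62, motif_plan=((2, 2),)))
        s = classify_proteome(recs, min_motifs=2, genome_id="syn")
        assert (s.n_mhc, s.n_motifs_in_mhc) == (2, 4)

    def test_mixed_plan_census(self):
        recs = synth_proteome(SimConfig(seed=63, motif_plan=((5, 1), (5, 3))))
        s = classify_proteome(recs, min_motifs=1, genome_id="syn")
        assert (s.n_mhc, s.n_motifs_in_mhc) == (10, 20)
        s2 = classify_proteome(recs, min_motifs=2, genome_id="syn")
        assert (s2.n_mhc, s2.n_motifs_in_mhc) == (5, 15)

    def test_counts_match_scanner_exactly(self):
        cfg = SimConfig(seed=64)
        recs = synth_proteome(cfg)
        got = sorted(len(scan_heme_motifs(r.sequence)) for r in recs)
        want = sorted(
            m for count, m in cfg.motif_plan for _ in range(count)
        )
        assert got == want

    def test_bit_reproducible(self):
        cfg = SimConfig(seed=65)
        assert synth_proteome(cfg) == synth_proteome(cfg)
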