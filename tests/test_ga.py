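"""GA fitness, evolution, determinism and the model/results surface."""

from __future__ import annotations

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssir.ga import (FitnessWeights, GAConfig, GroupingModel, Partition,
                     PartitionEvaluator, evolve, group_fitness,
                     partition_fitness, select_best_pair)
from ssir.merging import MergeStats, apply_scales, scale_to_reference


class FakeStats:
    def __init__(self, r_meas=0.2, i_over_sig=5.0, cc_half=0.95,
                 completeness=0.9, multiplicity=10.0):
        self.r_meas = r_meas
        self.i_over_sig = i_over_sig
        self.cc_half = cc_half
        self.completeness = completeness
        self.multiplicity = multiplicity


def tiny_config(**kw):
    base = dict(k=2, population_size=30, generations=15, seed=4,
                min_group_size=2, iso_min_common=20)
    base.update(kw)
    return GAConfig(**base)


@pytest.fixture(scope="module")
def scaled_tiny(tiny_pool):
    pool, truth = tiny_pool
    return apply_scales(pool, scale_to_reference(pool, min_common=10)), truth


class TestGroupFitness:
    def test_hand_arithmetic(self):
        w = FitnessWeights(1, 1, 1, 1, 1, 0)
        # (100-20) + 5 + 95 + 90 + 10 = 280
        assert group_fitness(FakeStats(), w) == pytest.approx(280.0)

    def test_only_r_weight_perfect_data(self):
        w = FitnessWeights(w_r=3.0, w_isig=0, w_cc=0, w_completeness=0,
                           w_multiplicity=0, w_iso=0)
        assert group_fitness(FakeStats(r_meas=0.0), w) == pytest.approx(300.0)

    def test_undefined_weighted_stat_penalized(self):
        w = FitnessWeights()
        assert group_fitness(FakeStats(cc_half=None), w) == -1.0e6

    def test_undefined_unweighted_stat_ignored(self):
        w = FitnessWeights(w_cc=0.0)
        assert group_fitness(FakeStats(cc_half=None), w) == pytest.approx(185.0)

    def test_weights_validation(self):
        with pytest.raises(ValueError):
            FitnessWeights(-1, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            FitnessWeights(0, 0, 0, 0, 0, 0)


class TestPartitionFitness:
    def test_label_permutation_invariance(self, scaled_tiny):
        pool, _ = scaled_tiny
        ev = PartitionEvaluator(pool, tiny_config())
        labels = np.array([0, 1, 0, 1, 1, 0])
        assert ev.partition_fitness(labels) == ev.partition_fitness(1 - labels)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.lists(st.integers(0, 2), min_size=6, max_size=6))
    def test_label_permutation_invariance_k3(self, scaled_tiny, labels):
        pool, _ = scaled_tiny
        ev = getattr(self, "_ev", None)
        if ev is None or ev.pool is not pool:
            ev = PartitionEvaluator(pool, tiny_config(k=3, min_group_size=1))
            self._ev = ev
        labels = np.array(labels)
        perm = np.array([2, 0, 1])
        assert ev.partition_fitness(labels) == pytest.approx(
            ev.partition_fitness(perm[labels]), rel=1e-12)

    def test_infeasible_partition_penalized(self, scaled_tiny):
        pool, _ = scaled_tiny
        ev = PartitionEvaluator(pool, tiny_config())
        assert ev.partition_fitness(np.array([0, 0, 0, 0, 0, 1])) == -1.0e6

    def test_evaluation_order_independence(self, scaled_tiny):
        pool, _ = scaled_tiny
        cfg = tiny_config()
        labelings = [np.array(x) for x in itertools.product([0, 1], repeat=6)]
        ev1 = PartitionEvaluator(pool, cfg)
        fits1 = [ev1.partition_fitness(l) for l in labelings]
        ev2 = PartitionEvaluator(pool, cfg)
        fits2 = [ev2.partition_fitness(l) for l in reversed(labelings)][::-1]
        np.testing.assert_array_equal(fits1, fits2)

    def test_wrapper_accepts_one_based_labels(self, scaled_tiny):
        pool, _ = scaled_tiny
        cfg = tiny_config()
        a = partition_fitness(np.array([1, 2, 1, 2, 2, 1]), pool, cfg)
        b = partition_fitness(np.array([0, 1, 0, 1, 1, 0]), pool, cfg)
        assert a == b

    def test_fitness_stats_match_compute_stats(self, scaled_tiny):
        """The evaluator's R/I/C/M ingredients equal the reporting module's."""
        from ssir.merging import compute_stats, merge

        pool, _ = scaled_tiny
        ev = PartitionEvaluator(pool, tiny_config())
        members = frozenset(range(3))
        score = ev.group_score(members)
        ids = [pool.dataset_ids[i] for i in members]
        grp = merge(pool, ids)
        st_ = compute_stats(grp, pool, shells=ev.shells)
        assert score.r_meas == pytest.approx(st_.r_meas, abs=1e-12)
        assert score.i_over_sig == pytest.approx(st_.i_over_sig, abs=1e-9)
        assert score.completeness == pytest.approx(st_.completeness, abs=1e-12)
        assert score.multiplicity == pytest.approx(st_.multiplicity, abs=1e-12)


class TestEvolve:
    def test_reaches_exhaustive_optimum(self, scaled_tiny):
        pool, _ = scaled_tiny
        cfg = tiny_config()
        ev = PartitionEvaluator(pool, cfg)
        best_exhaustive = max(
            ev.partition_fitness(np.array(lab))
            for lab in itertools.product([0, 1], repeat=6)
        )
        part, traj = evolve(pool, cfg, evaluator=ev)
        assert traj[-1].best_fitness == pytest.approx(best_exhaustive)

    def test_monotone_best_fitness(self, scaled_tiny):
        pool, _ = scaled_tiny
        part, traj = evolve(pool, tiny_config(seed=9))
        fits = [t.best_fitness for t in traj]
        assert all(a <= b for a, b in zip(fits, fits[1:]))

    def test_seed_reproducibility_and_divergence(self, scaled_tiny):
        pool, _ = scaled_tiny
        p1, t1 = evolve(pool, tiny_config(seed=5))
        p2, t2 = evolve(pool, tiny_config(seed=5))
        assert [r.to_json() for r in t1] == [r.to_json() for r in t2]
        assert np.array_equal(p1.labels, p2.labels)
        _, t3 = evolve(pool, tiny_config(seed=6))
        assert [r.to_json() for r in t1] != [r.to_json() for r in t3]

    def test_too_small_pool_rejected(self, scaled_tiny):
        pool, _ = scaled_tiny
        with pytest.raises(ValueError):
            evolve(pool, tiny_config(k=4))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(k=1)
        with pytest.raises(ValueError):
            GAConfig(population_size=2, elitism_count=2)
        with pytest.raises(ValueError):
            GAConfig(iso_ratio_direction="sideways")


class TestSelectBestPair:
    def test_k2_emits_both_orderings(self, scaled_tiny):
        pool, truth = scaled_tiny
        cfg = tiny_config()
        part, _ = evolve(pool, cfg)
        pair, report, manifest = select_best_pair(part, pool, cfg)
        assert pair == (0, 1)
        assert manifest["orderings"] == [
            {"native": 0, "derivative": 1},
            {"native": 1, "derivative": 0},
        ]
        assert report.defined

    def test_k4_selects_high_contrast_pair(self):
        from ssir.simulate import PoolSpec, simulate_pool

        spec = PoolSpec(d_min=3.0, n_native=8, n_derivative=8,
                        coverage_fraction=0.6, seed=77)
        pool, truth = simulate_pool(spec)
        cfg = GAConfig(k=4, population_size=40, generations=20, seed=7)
        model = GroupingModel(pool, cfg, truth=truth)
        res = model.fit()
        assert res.truth_ari() >= 0.9


class TestModelSurface:
    def test_fit_summary_and_save(self, tiny_pool, tmp_path):
        pool, truth = tiny_pool
        cfg = tiny_config()
        model = GroupingModel(pool, cfg, truth=truth)
        res = model.fit()
        text = res.summary()
        assert "best pair" in text and "groups: 2" in text
        paths = res.save(tmp_path)
        assert paths["partition"].exists()
        lines = paths["trajectory"].read_text().splitlines()
        assert len(lines) >= cfg.generations + 1
        rec = json.loads(lines[-1])
        assert rec["best_fitness"] >= json.loads(lines[0])["best_fitness"]
        manifest = json.loads(paths["manifest"].read_text())
        assert len(manifest["orderings"]) == 2
        assert paths["stats"].exists()
        assert (tmp_path / "group_1.hkl").exists()

    def test_truth_ari_against_sklearn(self, tiny_pool):
        from sklearn.metrics import adjusted_rand_score

        from ssir.util import adjusted_rand_index

        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 3, size=30)
            b = rng.integers(0, 4, size=30)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12)

    def test_plot_trajectory(self, tiny_pool, tmp_path):
        pool, truth = tiny_pool
        model = GroupingModel(pool, tiny_config())
        res = model.fit()
        fig = res.plot_trajectory(tmp_path / "traj.png")
        assert (tmp_path / "traj.png").exists()


class TestPartitionContainer:
    def test_members_and_sizes(self):
        p = Partition(np.array([0, 1, 1, 0]), ["a", "b", "c", "d"], k=2)
        assert p.members(0) == ["a", "d"]
        assert p.group_sizes().tolist() == [2, 2]
        assert p.one_based.tolist() == [1, 2, 2, 1]

    def test_label_range_validated(self):
        with pytest.raises(ValueError):
            Partition(np.array([0, 2]), ["a", "b"], k=2)
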