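"""Scaling, merging and the merging statistics against literal-formula oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ssir.cells import UnitCell
from ssir.merging import (ShellScheme, apply_scales, cc_half,
                          cell_range_report, choose_reference, compute_stats,
                          inner_shell_rmeas, merge, scale_to_reference,
                          theoretical_unique)
from ssir.simulate import PoolSpec, simulate_pool
from ssir.symmetry import get_symmetry, map_to_asu
from tests.conftest import make_table, random_pool


def oracle_stats(pool, member_ids=None):
    """Literal-formula R factors / <I/sig> / multiplicity via plain loops."""
    sub = pool.subset(member_ids) if member_ids else pool
    sym = sub.symmetry
    groups: dict[tuple, list] = {}
    for row in sub.df.itertuples(index=False):
        key = map_to_asu(int(row.h), int(row.k), int(row.l), sym)
        groups.setdefault(key, []).append((row.intensity, row.sigma))
    num_merge = num_meas = num_pim = denom = 0.0
    isig = []
    n_obs = 0
    for obs in groups.values():
        ii = np.array([o[0] for o in obs])
        ss = np.array([o[1] for o in obs])
        n = len(ii)
        n_obs += n
        w = 1.0 / ss**2
        i_m = np.sum(w * ii) / np.sum(w)
        isig.append(i_m * np.sqrt(np.sum(w)))
        if n >= 2:
            dev = np.abs(ii - ii.mean()).sum()
            num_merge += dev
            num_meas += np.sqrt(n / (n - 1)) * dev
            num_pim += np.sqrt(1.0 / (n - 1)) * dev
            denom += ii.sum()
    r = lambda num: (num / denom) if denom > 0 else None
    any_multi = any(len(o) >= 2 for o in groups.values())
    return {
        "r_merge": r(num_merge) if any_multi else None,
        "r_meas": r(num_meas) if any_multi else None,
        "r_pim": r(num_pim) if any_multi else None,
        "i_over_sig": float(np.mean(isig)),
        "multiplicity": n_obs / len(groups),
        "n_unique": len(groups),
        "n_obs": n_obs,
    }


class TestChooseReference:
    def test_highest_mean_i_over_sigma(self):
        t = make_table([
            ("a", 1, 0, 0, 3.1, 1.0), ("a", 2, 0, 0, 3.1, 1.0),
            ("b", 1, 0, 0, 2.2, 1.0),
        ])
        assert choose_reference(t) == "a"

    def test_tie_breaks_lexicographically(self):
        t = make_table([("zz", 1, 0, 0, 5.0, 1.0), ("aa", 2, 0, 0, 5.0, 1.0)])
        assert choose_reference(t) == "aa"

    def test_equals_brute_force_argmax(self):
        rng = np.random.default_rng(1)
        pool = random_pool(rng, n_datasets=5)
        snr = pool.df["intensity"] / pool.df["sigma"]
        means = snr.groupby(pool.df["dataset_id"]).mean()
        assert choose_reference(pool) == means.idxmax()


class TestScaling:
    def test_exact_factor_of_two(self):
        recs = [("ref", h, 0, 0, 10.0 * h, 1.0) for h in range(1, 30)]
        recs += [("half", h, 0, 0, 5.0 * h, 0.5) for h in range(1, 30)]
        pool = make_table(recs)
        scales = scale_to_reference(pool, "ref")
        assert scales["ref"] == 1.0
        assert scales["half"] == pytest.approx(2.0, rel=1e-12)

    def test_identical_dataset_scale_one(self):
        recs = [("ref", h, 0, 0, 7.0 * h, 1.0) for h in range(1, 25)]
        recs += [("dup", h, 0, 0, 7.0 * h, 1.0) for h in range(1, 25)]
        scales = scale_to_reference(make_table(recs), "ref")
        assert scales["dup"] == pytest.approx(1.0, rel=1e-12)

    def test_noisy_scale_recovered_within_one_percent(self):
        rng = np.random.default_rng(7)
        recs = []
        base = rng.gamma(2, 100, size=150)
        for h, b in enumerate(base, start=1):
            recs.append(("ref", h, 0, 1, float(b + rng.normal(0, 1)), 2.0))
            recs.append(("d", h, 0, 1, float(b / 3.0 + rng.normal(0, 0.5)), 0.7))
        scales = scale_to_reference(make_table(recs), "ref")
        assert scales["d"] == pytest.approx(3.0, rel=0.01)

    def test_unscalable_dataset_flagged(self, caplog):
        recs = [("ref", h, 0, 0, 5.0, 1.0) for h in range(1, 30)]
        recs += [("lonely", 0, 0, h, 5.0, 1.0) for h in range(1, 5)]
        with caplog.at_level("WARNING", logger="ssir"):
            scales = scale_to_reference(make_table(recs), "ref")
        assert np.isnan(scales["lonely"])
        assert "lonely" in caplog.text
        scaled = apply_scales(make_table(recs), scales)
        assert scaled.dataset_ids == ["ref"]


class TestMerge:
    def test_inverse_variance_mean(self):
        grp = merge(make_table([("a", 1, 2, 3, 10.0, 1.0), ("b", 1, 2, 3, 12.0, 1.0)]))
        assert grp.intensity[0] == pytest.approx(11.0)
        assert grp.sigma[0] == pytest.approx(1.0 / np.sqrt(2.0))
        assert grp.n_obs[0] == 2

    def test_single_observation_passthrough(self):
        grp = merge(make_table([("a", 1, 2, 3, 10.0, 2.5)]))
        assert grp.intensity[0] == pytest.approx(10.0)
        assert grp.sigma[0] == pytest.approx(2.5)

    def test_self_duplicate_halves_variance(self):
        one = [("a", 1, 2, 3, 8.0, 2.0)]
        dup = one + [("b", 1, 2, 3, 8.0, 2.0)]
        g1, g2 = merge(make_table(one)), merge(make_table(dup))
        assert g2.intensity[0] == pytest.approx(g1.intensity[0])
        assert g2.sigma[0] == pytest.approx(g1.sigma[0] / np.sqrt(2.0))

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            merge(make_table([("a", 1, 2, 3, 1.0, 0.1)]), [])

    def test_observation_count_preserved(self):
        rng = np.random.default_rng(3)
        pool = random_pool(rng)
        grp = merge(pool)
        assert grp.total_observations == len(pool)


class TestComputeStats:
    def test_hand_arithmetic_single_reflection(self):
        pool = make_table([("a", 1, 2, 3, 10.0, 1.0), ("b", 1, 2, 3, 12.0, 1.0)])
        st = compute_stats(merge(pool), pool)
        assert st.r_merge == pytest.approx(2.0 / 22.0)
        assert st.r_meas == pytest.approx(np.sqrt(2.0) * 2.0 / 22.0)
        assert st.r_pim == pytest.approx(2.0 / 22.0)
        assert st.multiplicity == pytest.approx(2.0)

    def test_exact_duplicates_zero_r(self):
        recs = [(d, h, k, l, 5.0 + h, 1.0) for d in "ab"
                for h in (1, 2) for k in (0, 1) for l in (0, 2) if (h, k, l) != (0, 0, 0)]
        pool = make_table(recs)
        st = compute_stats(merge(pool), pool)
        assert st.r_merge == 0.0 and st.r_meas == 0.0 and st.r_pim == 0.0
        assert st.cc_half == pytest.approx(1.0)

    def test_matches_literal_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(10):
            pool = random_pool(rng, n_datasets=rng.integers(2, 5),
                               n_unique=rng.integers(10, 40))
            st = compute_stats(merge(pool), pool)
            ora = oracle_stats(pool)
            for key in ("r_merge", "r_meas", "r_pim", "i_over_sig", "multiplicity"):
                if ora[key] is None:
                    assert getattr(st, key) is None
                else:
                    assert getattr(st, key) == pytest.approx(ora[key], abs=1e-12), key
            assert st.n_unique == ora["n_unique"]
            assert st.multiplicity * st.n_unique == pytest.approx(st.n_obs)

    def test_single_observations_give_undefined_r(self):
        pool = make_table([("a", 1, 0, 0, 5.0, 1.0), ("a", 2, 0, 0, 7.0, 1.0)])
        st = compute_stats(merge(pool), pool)
        assert st.r_merge is None and st.r_meas is None and st.r_pim is None

    def test_global_scale_invariance(self):
        rng = np.random.default_rng(5)
        pool = random_pool(rng)
        df = pool.df.copy()
        df["intensity"] *= 37.0
        df["sigma"] *= 37.0
        scaled = type(pool)(df, pool.cells, pool.symmetry)
        a = compute_stats(merge(pool), pool)
        b = compute_stats(merge(scaled), scaled)
        for key in ("r_merge", "r_meas", "r_pim", "i_over_sig",
                    "completeness", "multiplicity"):
            assert getattr(a, key) == pytest.approx(getattr(b, key), rel=1e-9)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            pool = random_pool(rng)
            st = compute_stats(merge(pool), pool)
            if st.r_merge is not None:
                assert st.r_pim <= st.r_merge <= st.r_meas


class TestCCHalf:
    def test_duplicates_give_one(self):
        recs = [(d, h, k, 1, float(10 * h + k), 1.0) for d in "ab"
                for h in range(1, 4) for k in range(3)]
        pool = make_table(recs)
        assert cc_half(merge(pool), pool, seed=0) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(2)
        recs = []
        for h in range(1, 80):
            for d in range(4):
                recs.append((f"d{d}", h, 1, 1, float(rng.normal(100.0, 30.0)), 1.0))
        pool = make_table(recs, cell=UnitCell(90, 90, 90))
        cc = cc_half(merge(pool), pool, seed=1, n_splits=40)
        assert abs(cc) < 0.25

    def test_seed_determinism(self, tiny_pool):
        pool, _ = tiny_pool
        grp = merge(pool, pool.dataset_ids[:3])
        assert cc_half(grp, pool, seed=5) == cc_half(grp, pool, seed=5)
        assert cc_half(grp, pool, seed=5) != cc_half(grp, pool, seed=6)

    def test_insufficient_data_undefined(self):
        pool = make_table([("a", 1, 0, 0, 5.0, 1.0)])
        assert cc_half(merge(pool), pool) is None

    def test_noise_monotonically_degrades_cc(self):
        rng = np.random.default_rng(4)
        base = rng.gamma(2, 100, size=60)
        ccs = []
        for noise in (1.0, 10.0, 40.0, 90.0, 200.0):
            recs = []
            for h, b in enumerate(base, start=1):
                for d in range(4):
                    recs.append((f"d{d}", h, 0, 1, float(b + rng.normal(0, noise)), 1.0))
            pool = make_table(recs, cell=UnitCell(70, 70, 70))
            ccs.append(cc_half(merge(pool), pool, seed=0, n_splits=30))
        assert all(a > b for a, b in zip(ccs, ccs[1:]))


class TestShellsAndRanges:
    def test_shell_scheme_equal_reciprocal_volume(self):
        sch = ShellScheme.equal_volume(2.0, 20.0, 10)
        vols = np.diff(sch.boundaries ** -3.0)
        np.testing.assert_allclose(vols, vols[0], rtol=1e-9)
        assert sch.boundaries[0] == pytest.approx(20.0)
        assert sch.boundaries[-1] == pytest.approx(2.0)
        assert (np.diff(sch.boundaries) < 0).all()

    def test_inner_shell_rmeas_single_low_res_reflection(self):
        pool = make_table([("a", 1, 0, 0, 10.0, 1.0), ("b", 1, 0, 0, 12.0, 1.0),
                           ("a", 8, 8, 8, 100.0, 1.0), ("b", 8, 8, 8, 150.0, 1.0)])
        grp = merge(pool)
        r = inner_shell_rmeas(grp, pool)
        assert r == pytest.approx(np.sqrt(2.0) * 2.0 / 22.0)

    def test_inner_shell_matches_oracle_subset(self):
        rng = np.random.default_rng(11)
        pool = random_pool(rng, n_datasets=4, n_unique=60)
        grp = merge(pool)
        from ssir.merging import pool_d_range
        d0, d1 = pool_d_range(pool)
        shells = ShellScheme.equal_volume(d0, d1, 10)
        # oracle: keep only observations whose ASU representative is in shell 0
        from ssir.cells import resolution
        asu = pool.asu_hkl()
        d = resolution(asu, pool.mean_cell())
        mask = shells.shell_of(d) == 0
        sub_df = pool.df[mask].reset_index(drop=True)
        sub = type(pool)(sub_df, pool.cells, pool.symmetry)
        expected = oracle_stats(sub)["r_meas"]
        got = inner_shell_rmeas(grp, pool, shells)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected, abs=1e-12)

    def test_cell_range_report(self):
        cells = {"a": UnitCell(77.5, 77.5, 38.0), "b": UnitCell(78.2, 78.2, 38.4)}
        pool = make_table([("a", 1, 0, 0, 1.0, 0.1), ("b", 1, 0, 0, 1.0, 0.1)],
                          cells=cells)
        rep = cell_range_report(merge(pool))
        a_row = rep[rep.axis == "a"].iloc[0]
        assert (a_row["min"], a_row["mean"], a_row["max"]) == (77.5, 77.85, 78.2)

    def test_grouped_ranges_narrower_than_pool(self):
        spec = PoolSpec(seed=3, d_min=3.0, n_native=6, n_derivative=6,
                        cell_offset_native=-0.004, cell_offset_derivative=0.004)
        pool, truth = simulate_pool(spec)
        lab = dict(zip(truth.table.dataset_id, truth.table.label))
        whole = cell_range_report(merge(pool))
        for label in ("native", "derivative"):
            grp = cell_range_report(merge(pool, [d for d in pool.dataset_ids
                                                 if lab[d] == label]))
            width_g = (grp["max"] - grp["min"]).to_numpy()[:3]
            width_p = (whole["max"] - whole["min"]).to_numpy()[:3]
            assert (width_g < width_p).all()


class TestTheoreticalUnique:
    def test_completeness_denominator(self, tiny_pool):
        pool, _ = tiny_pool
        ref = theoretical_unique(pool)
        st = compute_stats(merge(pool), pool, reference_unique=ref)
        assert st.completeness == pytest.approx(st.n_unique / len(ref))
        assert 0.9 < st.completeness <= 1.0
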