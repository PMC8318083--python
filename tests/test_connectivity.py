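"""RDMs, directed flow grids, direction-contrast inference."""

import numpy as np
import pytest

import semcomp as sc
from semcomp.connectivity import RDM_CONDITIONS


def tensor_from_patterns(patterns_by_cond, n_trials=6, tstep=5.0):
    """Build a one-subject TrialTensor with exact per-condition patterns."""
    conds, datas = [], []
    for cond in sc.CONDITIONS:
        pat = patterns_by_cond.get(cond)
        n_src, n_time = next(iter(patterns_by_cond.values())).shape
        block = np.tile(pat if pat is not None else np.zeros((n_src, n_time)), (n_trials, 1, 1))
        datas.append(block)
        conds += [cond] * n_trials
    rng = np.random.default_rng(0)
    n = len(conds)
    return sc.TrialTensor(
        np.concatenate(datas), np.array(conds), rng.normal(3, 1, n), rng.normal(3, 1, n),
        subject_id="00", tstart_ms=0.0, tstep_ms=tstep,
    )


class TestRDM:
    def test_identical_patterns_give_zero_dissimilarity(self):
        rng = np.random.default_rng(1)
        p = rng.normal(size=(5, 4))
        t = tensor_from_patterns({c: p for c in RDM_CONDITIONS})
        rdm = sc.compute_rdm_series(t, np.arange(5), granularity="condition", n_pseudo=3)
        assert np.allclose(rdm.rdm, 0.0, atol=1e-12)

    def test_opposite_centered_patterns_give_two(self):
        p = np.array([[1.0], [2.0], [3.0], [4.0]])
        q = 2 * p.mean() - p  # exactly anti-correlated after centering
        pats = {c: (p if c.startswith("HA") else q) for c in RDM_CONDITIONS}
        t = tensor_from_patterns(pats)
        rdm = sc.compute_rdm_series(t, np.arange(4), granularity="condition", n_pseudo=3)
        labels = rdm.pair_labels
        for k, (a, b) in enumerate(labels):
            expected = 0.0 if a[:2] == b[:2] else 2.0
            assert np.isclose(rdm.rdm[0, k], expected, atol=1e-12), (a, b)

    def test_three_item_rdm_matches_hand_computation(self):
        # 4-source toy patterns; pairwise 1 - Pearson r computed by hand
        pa = np.array([1.0, 2.0, 3.0, 4.0])
        pb = np.array([2.0, 1.0, 4.0, 3.0])
        pc_ = np.array([4.0, 3.0, 2.0, 1.0])
        def one_minus_r(u, v):
            return 1.0 - np.corrcoef(u, v)[0, 1]
        pats = {
            "HA-comp": pa[:, None], "LA-comp": pb[:, None],
            "HA-list": pc_[:, None], "LA-list": pa[:, None],
        }
        t = tensor_from_patterns(pats)
        rdm = sc.compute_rdm_series(t, np.arange(4), granularity="condition", n_pseudo=3)
        expected = {
            ("HA-comp", "LA-comp"): one_minus_r(pa, pb),
            ("HA-comp", "HA-list"): one_minus_r(pa, pc_),
            ("HA-comp", "LA-list"): 0.0,
            ("LA-comp", "HA-list"): one_minus_r(pb, pc_),
            ("LA-comp", "LA-list"): one_minus_r(pb, pa),
            ("HA-list", "LA-list"): one_minus_r(pc_, pa),
        }
        for k, pair in enumerate(rdm.pair_labels):
            assert np.isclose(rdm.rdm[0, k], expected[pair], atol=1e-12), pair

    def test_pseudo_trial_granularity_vector_length(self, space, noisy_dataset):
        t = sc.preprocess_for_patterns(noisy_dataset[0], 5)
        rdm = sc.compute_rdm_series(
            t, space.mask("roi_A"), granularity="pseudo-trial", n_pseudo=5
        )
        n_items = 4 * 5
        assert rdm.rdm.shape == (t.n_time, n_items * (n_items - 1) // 2)

    def test_tiny_region_rejected(self, noisy_dataset):
        with pytest.raises(ValueError, match="3 sources"):
            sc.compute_rdm_series(noisy_dataset[0], np.array([0, 1]))


class TestDirectedFlow:
    def _series(self, rdm, tstep=5.0, region="A"):
        n_time = rdm.shape[0]
        return sc.RDMSeries(
            region=region,
            times_ms=np.arange(n_time) * tstep,
            rdm=rdm,
            item_labels=tuple(RDM_CONDITIONS),
        )

    def test_constant_target_gives_zero_grid(self):
        rng = np.random.default_rng(2)
        src = self._series(rng.uniform(0, 2, size=(100, 6)))
        dst = self._series(np.full((100, 6), 0.7), region="B")
        grid = sc.directed_flow(src, dst, t_window_ms=(200.0, 500.0), dt_max_ms=100.0)
        vals = grid.pc[np.isfinite(grid.pc)]
        assert np.allclose(vals, 0.0)

    def test_planted_lag_peaks_in_dt_profile(self):
        lag_steps, tstep = 20, 5.0  # 100 ms
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 2, size=(240, 6))
        src = self._series(base)
        noise = 0.05 * rng.standard_normal((240, 6))
        dst_rdm = np.clip(np.roll(base, lag_steps, axis=0) + noise, 0, 2)
        dst = self._series(dst_rdm, region="B")
        grid = sc.directed_flow(src, dst, t_window_ms=(600.0, 1200.0), dt_max_ms=300.0, dt_step_ms=5.0)
        profile = np.nanmean(grid.pc, axis=0)
        assert grid.dt_axis_ms[np.nanargmax(profile)] == lag_steps * tstep

    def test_out_of_range_lags_marked_missing(self):
        rng = np.random.default_rng(4)
        src = self._series(rng.uniform(0, 2, (50, 6)))
        dst = self._series(rng.uniform(0, 2, (50, 6)), region="B")
        grid = sc.directed_flow(src, dst, t_window_ms=(50.0, 150.0), dt_max_ms=200.0)
        # t = 50 ms with dt > 50 ms reaches before the series start
        assert np.isnan(grid.pc[0, grid.dt_axis_ms > 50.0]).all()
        assert np.isfinite(grid.pc[0, grid.dt_axis_ms <= 50.0]).all()

    def test_swapping_roles_changes_conditioning(self):
        rng = np.random.default_rng(5)
        a = self._series(rng.uniform(0, 2, (120, 6)), region="A")
        b = self._series(rng.uniform(0, 2, (120, 6)), region="B")
        ab = sc.directed_flow(a, b, t_window_ms=(300.0, 500.0), dt_max_ms=100.0)
        ba = sc.directed_flow(b, a, t_window_ms=(300.0, 500.0), dt_max_ms=100.0)
        assert ab.source == "A" and ab.target == "B"
        assert ba.source == "B" and ba.target == "A"
        assert not np.allclose(ab.pc, ba.pc, equal_nan=True)


class TestDirectionContrast:
    def test_identical_directions_give_zero_contrast(self, space):
        design = sc.DesignSpec(n_subjects=5, trials_per_condition=10)
        tensors, _ = sc.simulate_dataset(
            design, space, noise=sc.NoiseSpec(sensor_sd=1.0), seed=40
        )
        conn = sc.DirectedConnectivity(
            tensors, space, "roi_A", "roi_B", dt_max_ms=100.0, dt_step_ms=20.0
        )
        res = conn.fit(seed=0)
        stat = sc.direction_contrast_test(res.ab, res.ab, n_perm=50, seed=0)
        assert np.allclose(stat.stat, 0.0)
        assert not stat.significant(0.05).any()

    def test_contrast_antisymmetric_under_direction_swap(self, space):
        design = sc.DesignSpec(n_subjects=4, trials_per_condition=10)
        tensors, _ = sc.simulate_dataset(
            design, space, noise=sc.NoiseSpec(sensor_sd=1.0), seed=41
        )
        conn = sc.DirectedConnectivity(
            tensors, space, "roi_A", "roi_B", dt_max_ms=100.0, dt_step_ms=20.0
        )
        res = conn.fit(seed=0)
        fwd = np.stack([a.pc - b.pc for a, b in zip(res.ab, res.ba)])
        rev = np.stack([b.pc - a.pc for a, b in zip(res.ab, res.ba)])
        assert np.allclose(fwd, -rev, equal_nan=True)

    def test_scale_invariance_of_flow_grids(self, space):
        design = sc.DesignSpec(n_subjects=4, trials_per_condition=10)
        tensors, _ = sc.simulate_dataset(
            design, space, noise=sc.NoiseSpec(sensor_sd=1.0), seed=42
        )
        conn1 = sc.DirectedConnectivity(tensors, space, "roi_A", "roi_B",
                                        dt_max_ms=60.0, dt_step_ms=20.0)
        scaled = []
        for t in tensors:
            t2 = t.copy()
            t2.data = t2.data * 7.0
            scaled.append(t2)
        conn2 = sc.DirectedConnectivity(scaled, space, "roi_A", "roi_B",
                                        dt_max_ms=60.0, dt_step_ms=20.0)
        r1, r2 = conn1.fit(seed=1), conn2.fit(seed=1)
        for g1, g2 in zip(r1.ab, r2.ab):
            assert np.allclose(g1.pc, g2.pc, atol=1e-9, equal_nan=True)

    def test_planted_coupling_detected_at_lag_and_sign_flips(self, space):
        lag = 100.0
        design = sc.DesignSpec(n_subjects=12, trials_per_condition=15)
        results = {}
        for direction in ("fwd", "rev"):
            src, tgt = ("roi_A", "roi_B") if direction == "fwd" else ("roi_B", "roi_A")
            eff = sc.PlantedEffect(
                "pattern:per-condition", space.mask(src), (600.0, 1200.0), 1.0,
                effect_form="multivariate-pattern", pattern_seed=3,
            )
            cpl = sc.CouplingSpec(src, tgt, lag_ms=lag, gain=1.0, window_ms=(700.0, 1200.0))
            tensors, _ = sc.simulate_dataset(
                design, space, [eff], [cpl], noise=sc.NoiseSpec(sensor_sd=0.5), seed=43
            )
            conn = sc.DirectedConnectivity(
                tensors, space, "roi_A", "roi_B", dt_max_ms=200.0, dt_step_ms=5.0
            )
            res = conn.fit(seed=0)
            results[direction] = res
        dt_axis = results["fwd"].ab[0].dt_axis_ms
        prof_fwd = np.nanmean(results["fwd"].mean_grid("ab") - results["fwd"].mean_grid("ba"), axis=0)
        prof_rev = np.nanmean(results["rev"].mean_grid("ab") - results["rev"].mean_grid("ba"), axis=0)
        assert dt_axis[np.nanargmax(prof_fwd)] == lag
        assert dt_axis[np.nanargmin(prof_rev)] == lag
        stat = results["fwd"].direction_test(n_perm=500, seed=1)
        sig = stat.to_grid(stat.p, fill=1.0) <= 0.05
        assert sig.any()
        sig_dt = dt_axis[sig.any(axis=0)]
        assert np.all(np.abs(sig_dt - lag) <= 25.0)
        assert np.all(stat.to_grid(stat.stat)[sig] > 0)


class TestFroiUnion:
    def test_union_of_significant_sources(self, space):
        res1 = sc.StatResult(
            stat=np.zeros(6), tfce=np.zeros(6),
            p=np.array([0.01, 1, 1, 1, 1, 1]), n_permutations=10, tail="two-sided",
            grid_shape=(3, 2),
        )
        res2 = sc.StatResult(
            stat=np.zeros(6), tfce=np.zeros(6),
            p=np.array([1, 1, 1, 1, 0.04, 1]), n_permutations=10, tail="two-sided",
            grid_shape=(3, 2),
        )
        m1 = np.array([10, 11, 12])
        m2 = np.array([20, 21, 22])
        out = sc.froi_union([res1, res2], [m1, m2], alpha=0.05)
        assert out.tolist() == [10, 22]
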