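"""Statistical core: OLS, one-sample t, TFCE, permutation inference, partial r."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import semcomp as sc
from semcomp.space import lattice_edges
from semcomp.stats import collinear_columns


# ---------------------------------------------------------------------------
# OLS


class TestOLS:
    def test_exact_linear_fit_recovers_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        beta = np.array([1.5, -2.0, 0.3, 4.0])
        assert np.allclose(sc.ols_fit(X @ beta, X), beta, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(sc.ols_fit(y, X), oracle, atol=1e-8)

    def test_intercept_only_gives_mean(self):
        y = np.array([1.0, 2.0, 4.0, 9.0])
        assert np.isclose(sc.ols_fit(y, np.ones((4, 1)))[0], y.mean())

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        resid = y - X @ sc.ols_fit(y, X)
        assert np.allclose(X.T @ resid, 0.0, atol=1e-10)

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            sc.ols_fit(rng.normal(size=20), X)
        named = collinear_columns(X, ["a", "b", "c", "d"])
        assert named  # at least one of the dependent set is identified

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="more trials"):
            sc.ols_fit(np.ones(3), np.ones((3, 4)))


# ---------------------------------------------------------------------------
# one-sample t


class TestOneSampleT:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        x = rng.normal(2.0, 1.0, size=10)
        expected = (x.mean() - 2.0) / (x.std(ddof=1) / np.sqrt(10))
        assert np.isclose(sc.one_sample_t(x, 2.0), expected, atol=1e-12)

    def test_symmetric_sample_gives_zero(self):
        assert sc.one_sample_t(np.array([-1.0, 1.0]), 0.0) == 0.0

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t = sc.one_sample_t(np.array([2.0, 2.0, 2.0, 2.0]), 1.0)
        assert t == np.inf
        with pytest.warns(UserWarning, match="zero variance"):
            assert sc.one_sample_t(np.ones(4), 1.0) == 0.0


# ---------------------------------------------------------------------------
# TFCE


def tfce_bruteforce(stat2d, E, H, dh, h0=0.0):
    """Independent threshold-sweep oracle using scipy.ndimage labeling."""
    from scipy import ndimage

    out = np.zeros_like(stat2d)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    h = h0 + dh
    while h <= stat2d.max() + 1e-12:
        mask = stat2d >= h
        if not mask.any():
            break
        labels, n = ndimage.label(mask, structure=structure)
        sizes = np.bincount(labels.ravel())
        out[mask] += (sizes[labels[mask]] ** E) * (h ** H) * dh
        h += dh
    return out


class TestTFCE:
    def test_all_zero_map_enhances_to_zero(self):
        edges = lattice_edges((4, 5))
        assert np.all(sc.tfce_enhance(np.zeros(20), edges) == 0)

    def test_isolated_point_closed_form(self):
        # single supra-threshold point, extent 1 throughout:
        # integral of x^H from 0 to h -> h^(H+1)/(H+1); H=2 -> h^3/3
        edges = lattice_edges((3, 3))
        stat = np.zeros(9)
        stat[4] = 1.8
        tf = sc.tfce_enhance(stat, edges, sc.TFCEParams(E=0.5, H=2.0, n_steps=4000))
        assert np.isclose(tf[4], 1.8**3 / 3, rtol=2e-3)
        assert np.all(tf[np.arange(9) != 4] == 0)

    def test_matches_bruteforce_oracle_on_random_grid(self):
        rng = np.random.default_rng(5)
        stat = rng.standard_normal((15, 20))
        edges = lattice_edges((15, 20))
        dh = stat.max() / 1000
        mine = sc.tfce_enhance(
            stat.ravel(), edges, sc.TFCEParams(dh=dh), tail="one-sided-positive"
        )
        oracle = tfce_bruteforce(stat, 0.5, 2.0, dh / 10)
        err = np.abs(mine - oracle.ravel())
        assert np.all(err <= 0.01 * oracle.ravel() + 1e-4 * oracle.max())

    def test_two_sided_negates_negative_lobe(self):
        rng = np.random.default_rng(6)
        stat = rng.standard_normal(60)
        edges = lattice_edges((6, 10))
        signed = sc.tfce_enhance(stat, edges, tail="two-sided")
        assert np.all(signed[stat > 0] >= 0) and np.all(signed[stat < 0] <= 0)
        flipped = sc.tfce_enhance(-stat, edges, tail="two-sided")
        assert np.allclose(signed, -flipped)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_the_statistic_map(self, seed):
        rng = np.random.default_rng(seed)
        stat = rng.standard_normal(24)
        bump = np.abs(rng.standard_normal(24)) * 0.3
        edges = lattice_edges((4, 6))
        params = sc.TFCEParams(dh=0.02)
        lo = sc.tfce_enhance(stat, edges, params, tail="one-sided-positive")
        hi = sc.tfce_enhance(stat + bump, edges, params, tail="one-sided-positive")
        assert np.all(hi >= lo - 1e-12)

    def test_commutes_with_grid_relabeling(self):
        rng = np.random.default_rng(7)
        stat = rng.standard_normal(30)
        edges = lattice_edges((5, 6))
        perm = rng.permutation(30)
        inv = np.argsort(perm)
        relabeled_edges = inv[edges]
        params = sc.TFCEParams(dh=0.05)
        direct = sc.tfce_enhance(stat, edges, params)
        relabeled = sc.tfce_enhance(stat[perm], relabeled_edges, params)
        # value at original node i must equal value at its new label inv[i]
        assert np.allclose(direct, relabeled[inv])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sc.tfce_enhance(np.array([]), np.zeros((0, 2), dtype=int))


# ---------------------------------------------------------------------------
# permutation test


class TestPermutationTest:
    edges = lattice_edges((4, 6))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        maps = rng.standard_normal((6, 24))
        a = sc.permutation_test(maps, 0.0, self.edges, n_perm=50, seed=3)
        b = sc.permutation_test(maps, 0.0, self.edges, n_perm=50, seed=3)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.tfce, b.tfce)

    def test_huge_planted_effect_reaches_minimum_p(self):
        rng = np.random.default_rng(9)
        maps = rng.standard_normal((8, 24)) * 0.01
        maps[:, 10] += 50.0
        res = sc.permutation_test(maps, 0.0, self.edges, n_perm=99, seed=0)
        assert np.isclose(res.p[10], 1.0 / 100)

    def test_null_maps_mostly_nonsignificant(self):
        rng = np.random.default_rng(10)
        maps = rng.standard_normal((8, 24))
        res = sc.permutation_test(maps, 0.0, self.edges, n_perm=200, seed=1)
        assert res.p.min() > 0.01

    def test_pvalues_superuniform_under_null(self):
        # family-wise p from max-statistic correction must be conservative
        # pointwise: empirical CDF below uniform (plus simulation slack)
        rng = np.random.default_rng(11)
        fp = 0
        n_data = 60
        for d in range(n_data):
            maps = rng.standard_normal((8, 24))
            res = sc.permutation_test(maps, 0.0, self.edges, n_perm=60, seed=d)
            fp += res.significant(0.05).any()
        assert fp / n_data <= 0.125  # binomial upper band around 0.05

    def test_one_sided_ignores_negative_effects(self):
        rng = np.random.default_rng(12)
        maps = rng.standard_normal((8, 24)) * 0.01 - 5.0
        res = sc.permutation_test(
            maps, 0.0, self.edges, n_perm=99, seed=0, tail="one-sided-positive"
        )
        assert not res.significant(0.05).any()

    def test_zero_replacement_null_variant_runs(self):
        rng = np.random.default_rng(13)
        maps = rng.standard_normal((8, 24))
        res = sc.permutation_test(maps, 0.0, self.edges, n_perm=50, seed=0, null="zero")
        assert res.meta["null"] == "zero" and res.p.shape == (24,)

    def test_insufficient_permutations_warn(self):
        rng = np.random.default_rng(14)
        with pytest.warns(UserWarning, match="cannot reach"):
            sc.permutation_test(rng.standard_normal((5, 10)), 0.0, self.edges[:0], n_perm=5, seed=0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="4 subjects"):
            sc.permutation_test(np.ones((3, 5)), 0.0, np.zeros((0, 2), int), n_perm=10)


# ---------------------------------------------------------------------------
# partial correlation


class TestPartialCorrelation:
    def test_orthogonal_confound_reduces_to_plain_correlation(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        z = rng.normal(size=200)
        # orthogonalize z against x and y
        A = np.column_stack([np.ones(200), x, y])
        z = z - A @ np.linalg.lstsq(A, z, rcond=None)[0]
        expected = np.corrcoef(x, y)[0, 1]
        assert np.isclose(sc.partial_correlation(x, y, z), expected, atol=1e-12)

    def test_fully_explained_by_confound_gives_zero(self):
        rng = np.random.default_rng(16)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        assert abs(sc.partial_correlation(x, y, y.copy())) < 1e-12

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x, y, z = rng.normal(size=(3, 10))
            A = np.column_stack([np.ones(10), z])
            rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
            ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert np.isclose(sc.partial_correlation(x, y, z), oracle, atol=1e-10)

    def test_constant_input_returns_zero(self):
        x = np.ones(10)
        y = np.arange(10.0)
        assert sc.partial_correlation(x, y, y + 1) == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    def test_symmetry_and_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 12))
        r = sc.partial_correlation(x, y, z)
        assert np.isclose(r, sc.partial_correlation(y, x, z), atol=1e-12)
        assert np.isclose(
            r, sc.partial_correlation(scale * x + shift, y, z), atol=1e-9
        )
        assert np.isclose(
            r, sc.partial_correlation(x, y, scale * z + shift), atol=1e-9
        )
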