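"""SparCC core: pair bookkeeping, basis solve, recovery and permutation null."""

import numpy as np
import pytest

import syntronet as sn
from syntronet.errors import DegenerateDataError, ParameterError
from _oracles import basis_variance_closed_form


class TestPairBookkeeping:
    @pytest.mark.parametrize(
        "n,include_self,expected",
        [(3052, True, 4_658_878), (1, True, 1), (4, False, 6), (2, False, 1)],
    )
    def test_pair_counts(self, n, include_self, expected):
        assert sn.enumerate_pairs(n, include_self=include_self) == expected

    def test_invalid_n_rejected(self):
        with pytest.raises(ParameterError):
            sn.enumerate_pairs(0)


class TestFractions:
    def test_point_estimate_is_posterior_mean(self):
        np.testing.assert_allclose(
            sn.estimate_fractions(np.array([1, 1]), method="point"), [0.5, 0.5]
        )

    def test_dirichlet_draws_average_to_posterior_mean(self):
        rng = np.random.default_rng(0)
        draws = np.stack(
            [sn.estimate_fractions(np.array([8, 2]), rng=rng) for _ in range(10_000)]
        )
        np.testing.assert_allclose(draws.mean(axis=0), [0.75, 0.25], atol=0.01)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        frac = sn.estimate_fractions(rng.integers(0, 50, size=(10, 8)), rng=rng)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_row_rejected(self):
        with pytest.raises(DegenerateDataError):
            sn.estimate_fractions(np.zeros(4, dtype=int))


class TestLogRatioVariances:
    def test_identical_components_have_zero_variance(self):
        f = np.tile([0.2, 0.2, 0.6], (5, 1))
        T = sn.logratio_variance_matrix(f)
        assert T.t[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_two_sample_hand_variance(self):
        # ratios (e, 1): log-ratios {1, 0}, unbiased variance 0.5
        e = np.e
        f = np.array([[e / (1 + e), 1 / (1 + e)], [0.5, 0.5]])
        T = sn.logratio_variance_matrix(f)
        assert T.t[0, 1] == pytest.approx(0.5, rel=1e-12)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        f = rng.dirichlet(np.ones(6), size=12)
        T = sn.logratio_variance_matrix(f)
        assert np.allclose(T.t, T.t.T)
        assert np.all(np.diag(T.t) == 0)
        assert np.all(T.t >= 0)


class TestBasisSolve:
    def test_uniform_t_gives_unit_basis_variances(self):
        T = np.full((3, 3), 2.0)
        np.fill_diagonal(T, 0.0)
        basis = sn.solve_basis_variances(T)
        np.testing.assert_allclose(basis.omega_sq, [1.0, 1.0, 1.0], atol=1e-12)
        rho = sn.correlations_from_basis(T, basis)
        off = rho[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_proportional_pair_yields_zero_variance_flagged(self):
        # t_12 = 0, t_13 = t_23 = t: the solve gives w_1 = w_2 = 0 (clamped)
        t = 2.0
        T = np.array([[0.0, 0.0, t], [0.0, 0.0, t], [t, t, 0.0]])
        basis = sn.solve_basis_variances(T)
        assert basis.clamped[0] and basis.clamped[1]
        rho = sn.correlations_from_basis(T, basis)
        assert np.isnan(rho[0, 2])  # undefined where omega hit the floor

    def test_matches_closed_form_dense_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            D = int(rng.integers(4, 9))
            A = rng.uniform(0.1, 3.0, size=(D, D))
            t = 0.5 * (A + A.T)
            np.fill_diagonal(t, 0.0)
            got = sn.solve_basis_variances(t).omega_sq
            want = basis_variance_closed_form(t)
            want_clamped = np.where(want < 1e-12, 1e-12, want)
            np.testing.assert_allclose(got, want_clamped, atol=1e-10)

    def test_too_few_otus_rejected(self):
        with pytest.raises(DegenerateDataError):
            sn.solve_basis_variances(np.zeros((2, 2)))

    def test_algebraic_identity_t_from_omegas_gives_rho_one(self):
        w = np.array([1.0, 4.0, 9.0])
        om = np.sqrt(w)
        t = (om[:, None] - om[None, :]) ** 2
        basis = sn.BasisSystem(omega_sq=w, clamped=np.zeros(3, bool))
        rho = sn.correlations_from_basis(t, basis)
        off = rho[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-12)


class TestSparccEstimate:
    def test_fixed_seed_is_deterministic(self, random_table):
        a = sn.sparcc_correlations(random_table, seed=5)
        b = sn.sparcc_correlations(random_table, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_output_is_symmetric_unit_diagonal_bounded(self, random_table):
        rho = sn.sparcc_correlations(random_table, seed=1)
        assert np.allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert np.nanmax(np.abs(rho)) <= 1.0

    def test_planted_correlation_recovered_across_replicates(self):
        # rho_basis = 0.8 at 300 samples: median estimate within 0.1 in >=90%
        hits = 0
        for seed in range(20):
            cfg = sn.SimOtuConfig(
                n_samples=300, n_otus=40, planted_pairs=((0, 1, 0.8),), seed=seed
            )
            table = sn.gen_otu_table(cfg)
            rho = sn.sparcc_correlations(table, seed=100 + seed)
            hits += abs(rho[0, 1] - 0.8) <= 0.1
        assert hits >= 18

    def test_independent_otus_show_no_strong_correlation(self):
        cfg = sn.SimOtuConfig(n_samples=200, n_otus=50, seed=21)
        rho = sn.sparcc_correlations(sn.gen_otu_table(cfg), seed=2)
        off = np.abs(rho[np.triu_indices(50, k=1)])
        assert np.percentile(off, 95) < 0.3

    def test_scale_invariance_to_library_depth(self):
        # Re-drawing counts at 5x depth from the same basis moves rho little.
        base = dict(n_samples=300, n_otus=30, planted_pairs=((0, 1, 0.8),), seed=13)
        t1 = sn.gen_otu_table(sn.SimOtuConfig(**base))
        t2 = sn.gen_otu_table(sn.SimOtuConfig(**base, depth_mean=150_000.0))
        r1 = sn.sparcc_correlations(t1, seed=3)
        r2 = sn.sparcc_correlations(t2, seed=3)
        iu = np.triu_indices(30, k=1)
        assert np.mean(np.abs(r1[iu] - r2[iu])) < 0.05


class TestBootstrapPseudoP:
    def test_observed_above_all_nulls_is_significant(self):
        rho_obs = np.array([[1.0, 0.9], [0.9, 1.0]])
        # craft counts whose permutations cannot reach rho 0.9... instead check
        # the add-one arithmetic directly on the returned table
        cfg = sn.SimOtuConfig(n_samples=300, n_otus=10, planted_pairs=((0, 1, 0.95),), seed=4)
        table = sn.gen_otu_table(cfg)
        rho = sn.sparcc_correlations(table, seed=5)
        corr = sn.bootstrap_pseudo_p(table, rho, B=100, seed=6)
        assert corr.pseudo_p[0, 1] == pytest.approx(1 / 101)
        assert corr.pseudo_p[0, 1] < 0.01

    def test_observed_below_every_null_gets_p_one(self):
        cfg = sn.SimOtuConfig(n_samples=60, n_otus=8, seed=9)
        table = sn.gen_otu_table(cfg)
        rho = np.full((8, 8), -1.0)
        np.fill_diagonal(rho, 1.0)
        corr = sn.bootstrap_pseudo_p(table, rho, B=20, seed=1)
        iu = np.triu_indices(8, k=1)
        np.testing.assert_allclose(corr.pseudo_p[iu], 1.0)

    def test_permutation_preserves_column_multisets(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 40, size=(25, 6))
        perm = rng.permuted(counts, axis=0)
        for j in range(6):
            assert sorted(perm[:, j]) == sorted(counts[:, j])

    def test_null_pseudo_p_not_anticonservative(self):
        # independent basis data: P(pseudo_p < a) should not exceed a by more
        # than Monte-Carlo error, for each replicate table
        rates = []
        for seed in range(10):
            cfg = sn.SimOtuConfig(n_samples=60, n_otus=20, seed=30 + seed)
            table = sn.gen_otu_table(cfg)
            rho = sn.sparcc_correlations(table, n_inner=5, seed=seed)
            corr = sn.bootstrap_pseudo_p(table, rho, B=50, seed=60 + seed, n_inner=5)
            iu = np.triu_indices(20, k=1)
            rates.append(np.mean(corr.pseudo_p[iu] < 0.05))
        assert np.mean(rates) <= 0.05 + 0.02

    def test_invalid_bootstrap_count_rejected(self, random_table):
        rho = np.eye(random_table.n_otus)
        with pytest.raises(ParameterError):
            sn.bootstrap_pseudo_p(random_table, rho, B=0)


class TestSignificantPairs:
    def test_alpha_zero_gives_empty_list(self, random_table):
        rho = sn.sparcc_correlations(random_table, n_inner=3, seed=0)
        corr = sn.bootstrap_pseudo_p(random_table, rho, B=10, seed=1, n_inner=3)
        assert len(sn.significant_pairs(corr, alpha=0.0)) == 0

    def test_planted_pairs_all_detected(self):
        pairs = tuple((i, i + 5, 0.9) for i in range(5))
        cfg = sn.SimOtuConfig(n_samples=300, n_otus=30, planted_pairs=pairs, seed=17)
        table = sn.gen_otu_table(cfg)
        rho = sn.sparcc_correlations(table, seed=18)
        corr = sn.bootstrap_pseudo_p(table, rho, B=100, seed=19)
        sig = sn.significant_pairs(corr, alpha=0.01)
        called = {tuple(sorted((r.otu_i, r.otu_j))) for r in sig.itertuples()}
        planted = {
            tuple(sorted((table.otu_ids[i], table.otu_ids[j]))) for i, j, _ in pairs
        }
        assert planted <= called
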