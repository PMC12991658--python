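import numpy as np
import pytest
from scipy import stats

import finestab as fs
from finestab.errors import DegenerateInputError, EmptyInputError
from finestab.pics import (
    _permuted_phenotypes,
    _strata,
    enumerate_constrained_permutations,
)


class TestMarginalAssoc:
    def test_affine_copy_gives_one(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=50).astype(float)
        y = 3.0 * x - 7.0
        X = np.column_stack([x, rng.integers(0, 3, size=50)])
        assert fs.marginal_assoc(X, y)[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_variant_near_zero(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.integers(0, 3, size=(1000, 1)).astype(float)
            y = rng.normal(size=1000)
            hits += fs.marginal_assoc(X, y)[0] < 0.02
        assert hits >= 95

    def test_ranking_matches_regression_f_statistic(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(80, 12)).astype(float)
        y = X[:, 4] + rng.normal(size=80)
        r2 = fs.marginal_assoc(X, y)
        fstats = []
        for j in range(12):
            res = stats.linregress(X[:, j], y)
            df = 80 - 2
            fstats.append(df * res.rvalue**2 / (1 - res.rvalue**2))
        assert list(np.argsort(r2)) == list(np.argsort(fstats))

    def test_constant_phenotype_raises(self):
        X = np.random.default_rng(0).integers(0, 3, size=(20, 3)).astype(float)
        with pytest.raises(DegenerateInputError):
            fs.marginal_assoc(X, np.ones(20))

    def test_monomorphic_variant_scores_zero(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.full(30, 2.0), rng.integers(0, 3, 30)])
        y = rng.normal(size=30)
        assert fs.marginal_assoc(X, y)[0] == 0.0


class TestLeadSnp:
    def test_simple_argmax(self):
        assert fs.lead_snp(np.array([0.1, 0.9, 0.3])) == 1

    def test_position_tie_break(self):
        # equal statistics: variant with the smaller position wins
        assert fs.lead_snp(np.array([0.5, 0.5]), positions=np.array([200, 100])) == 1

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        assoc = rng.random(50)
        assert fs.lead_snp(assoc) == int(np.argmax(assoc))

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            idx = fs.lead_snp(np.zeros(4), positions=np.array([40, 10, 30, 20]))
        assert idx == 1  # smallest position


class TestNeighborhood:
    def test_isolated_lead(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 4))  # independent columns
        members = fs.neighborhood(X, lead=2, r_threshold=0.5)
        assert list(members) == [2]

    def test_duplicate_column_included(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 40).astype(float)
        X = np.column_stack([x, x.copy(), rng.normal(size=40)])
        members = fs.neighborhood(X, lead=0, r_threshold=0.5)
        assert 1 in members

    def test_matches_pairwise_filter(self, small_locus):
        lead = 7
        members = fs.neighborhood(small_locus, lead, r_threshold=0.5)
        X = small_locus.dosages
        brute = [
            k
            for k in range(X.shape[1])
            if k == lead or np.corrcoef(X[:, k], X[:, lead])[0, 1] ** 2 > 0.25
        ]
        assert sorted(members) == sorted(brute)


class TestConstrainedPermutation:
    def test_two_strata_shuffle_within(self):
        X = np.column_stack(
            [np.array([0.0, 0, 1, 1]), np.arange(4, dtype=float)]
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = fs.constrained_permutation(X, focal=0, rng=rng)
            assert set(perm[:2]) == {0, 1} and set(perm[2:]) == {2, 3}
            np.testing.assert_array_equal(X[perm][:, 0], X[:, 0])

    def test_constant_focal_allows_all_orders(self):
        X = np.column_stack([np.ones(4), np.arange(4, dtype=float)])
        rng = np.random.default_rng(0)
        seen = {tuple(fs.constrained_permutation(X, 0, rng)) for _ in range(500)}
        assert len(seen) == 24  # all 4! orders reachable

    def test_group_enumeration_and_uniformity(self):
        # strata sizes (3, 2, 1): the constrained group has 3!*2!*1! = 12 elements
        focal = np.array([0.0, 0, 0, 1, 1, 2])
        perms = enumerate_constrained_permutations(focal)
        assert len(perms) == 12
        assert len({tuple(p) for p in perms}) == 12
        X = np.column_stack([focal, np.arange(6, dtype=float)])
        rng = np.random.default_rng(123)
        counts = {tuple(p): 0 for p in perms}
        for _ in range(10_000):
            counts[tuple(fs.constrained_permutation(X, 0, rng))] += 1
        chi2 = sum((c - 10_000 / 12) ** 2 / (10_000 / 12) for c in counts.values())
        assert stats.chi2.sf(chi2, df=11) > 0.01

    def test_invariants_preserved_exactly(self, small_locus):
        X = small_locus.dosages
        y = np.random.default_rng(5).normal(size=X.shape[0])
        base_corr = np.corrcoef(X, rowvar=False)
        rng = np.random.default_rng(9)
        for _ in range(200):
            perm = fs.constrained_permutation(X, focal=3, rng=rng)
            Xp = X[perm]
            np.testing.assert_array_equal(Xp[:, 3], X[:, 3])
            # row multiset preserved exactly: canonical row order is byte-identical,
            # so every column-wise statistic (incl. correlations) is exactly invariant
            order_p = np.lexsort(Xp.T)
            order_0 = np.lexsort(X.T)
            assert Xp[order_p].tobytes() == X[order_0].tobytes()
            np.testing.assert_allclose(
                np.corrcoef(Xp, rowvar=False), base_corr, rtol=0, atol=1e-12
            )

    def test_inverse_permutation_equivalence(self):
        # permuting y by sigma is the same null as permuting rows of X:
        # the permuted-phenotype matrix columns are valid within-stratum shuffles
        focal = np.array([0.0, 0, 1, 1, 1])
        y = np.arange(5, dtype=float)
        Y = _permuted_phenotypes(y, focal, 50, np.random.default_rng(0))
        for col in Y.T:
            assert sorted(col[:2]) == [0, 1] and sorted(col[2:]) == [2, 3, 4]


class TestPicsPosterior:
    def test_singleton_neighborhood(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = X[:, 0] + rng.normal(size=100)
        vec = fs.pics_posterior(X, y, lead=0, members=np.array([0]))
        assert vec.probs.tolist() == [1.0]

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 6 samples, strata small enough to enumerate the constrained group
        rng = np.random.default_rng(21)
        X = np.column_stack(
            [
                np.array([0.0, 0, 1, 1, 2, 2]),
                np.array([0.0, 1, 1, 2, 2, 2]),
                np.array([0.0, 0, 0, 1, 2, 2]),
                np.array([2.0, 1, 0, 1, 0, 0]),
            ]
        )
        y = np.array([0.1, 0.3, 1.1, 0.9, 2.2, 1.8])
        assoc = fs.marginal_assoc(X, y)
        lead = fs.lead_snp(assoc)
        exact = fs.pics_posterior(X, y, lead, exhaustive=True)
        R = 5000
        params = fs.PicsParams(n_permutations=R, seed=77)
        mc = fs.pics_posterior(X, y, lead, params)
        np.testing.assert_array_equal(exact.support, mc.support)
        for p_ex, p_mc in zip(exact.probs, mc.probs):
            se = np.sqrt(max(p_ex * (1 - p_ex), 1e-4) / R)
            assert abs(p_mc - p_ex) <= 3 * se + 1e-9

    def test_sums_to_one_and_nonnegative(self, small_locus):
        y = np.random.default_rng(3).normal(size=small_locus.n_samples)
        assoc = fs.marginal_assoc(small_locus, y)
        lead = fs.lead_snp(assoc, small_locus.positions, small_locus.variant_ids)
        vec = fs.pics_posterior(
            small_locus, y, lead, fs.PicsParams(n_permutations=100, seed=1)
        )
        assert vec.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(vec.probs >= 0)


class TestPicsLoop:
    def test_supports_pairwise_disjoint(self, small_locus):
        y = np.random.default_rng(4).normal(size=small_locus.n_samples)
        result = fs.pics(small_locus, y, fs.PicsParams(n_permutations=50, seed=2))
        seen = set()
        for vec in result.pooled:
            assert not seen.intersection(vec.support.tolist())
            seen.update(vec.support.tolist())

    def test_exhaustion_yields_single_set(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=300)
        X = np.column_stack(
            [base + 0.3 * rng.normal(size=300) for _ in range(3)]
        )  # mutually |r| > 0.5
        y = base + rng.normal(size=300)
        corr = np.corrcoef(X, rowvar=False)
        assert np.all(np.abs(corr[np.triu_indices(3, 1)]) > 0.5)
        result = fs.pics(X, y, fs.PicsParams(n_potential_sets=3, n_permutations=50, seed=1))
        assert result.n_sets == 1

    def test_recovers_strong_causal_variant(self):
        hits = 0
        for seed in range(20):
            gm = fs.synth_genotypes(
                n_per_pop=(60,) * 5, n_variants=20, ld_rho=0.0,
                fst_like_drift=0.0, seed=seed,
            )
            phen = fs.simulate_phenotype(
                gm, fs.SimulationSpec(n_causal=1, phi=0.4, seed=seed + 1000)
            )
            result = fs.pics(
                gm, phen.values,
                fs.PicsParams(n_potential_sets=1, n_permutations=100, seed=seed),
            )
            vec = result.pooled[0]
            causal = phen.causal_indices[0]
            if causal in vec.support and vec.prob_of(causal) >= vec.probs.max() - 1e-12:
                hits += 1
        assert hits >= 18

    def test_bit_reproducible_given_seed(self, small_locus):
        y = np.random.default_rng(8).normal(size=small_locus.n_samples)
        params = fs.PicsParams(n_permutations=80, seed=99)
        a = fs.pics(small_locus, y, params)
        b = fs.pics(small_locus, y, params)
        for va, vb in zip(a.pooled, b.pooled):
            np.testing.assert_array_equal(va.support, vb.support)
            assert va.probs.tobytes() == vb.probs.tobytes()

    def test_prior_scale_invariance(self, small_locus):
        y = np.random.default_rng(8).normal(size=small_locus.n_samples)
        prior = np.random.default_rng(2).random(small_locus.n_variants) + 0.1
        a = fs.pics(small_locus, y, fs.PicsParams(n_permutations=60, seed=5, prior=prior))
        b = fs.pics(small_locus, y, fs.PicsParams(n_permutations=60, seed=5, prior=prior * 37.0))
        for va, vb in zip(a.pooled, b.pooled):
            assert list(np.argsort(va.probs)) == list(np.argsort(vb.probs))

    def test_monomorphic_matrix_raises(self):
        X = np.ones((10, 4))
        with pytest.raises(EmptyInputError):
            fs.pics(X, np.random.default_rng(0).normal(size=10))


class TestEstimator:
    def test_fit_predict_and_params(self, small_locus):
        y = np.random.default_rng(6).normal(size=small_locus.n_samples)
        est = fs.PicsFineMapper(n_permutations=50, random_state=4)
        assert est.get_params()["n_permutations"] == 50
        est.fit(small_locus, y)
        picks = est.predict()
        assert len(picks) == len(est.potential_sets_)
        for vec, pick in zip(est.potential_sets_, picks):
            assert pick in vec.support
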