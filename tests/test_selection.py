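import numpy as np
import pytest

import finestab as fs
from finestab.selection import _genotype_pcs
from finestab.data import PosteriorVector

from conftest import dense_vector


def random_sparse_vector(rng, n_variants, max_support=5):
    size = rng.integers(1, max_support + 1)
    support = np.sort(rng.choice(n_variants, size=size, replace=False))
    probs = rng.random(size)
    probs /= probs.sum()
    return PosteriorVector(
        support=support, probs=probs, lead_index=int(support[np.argmax(probs)])
    )


class TestResidualize:
    def test_orthogonal_phenotype_unchanged(self, small_locus):
        U = _genotype_pcs(small_locus.dosages, 5, scale=False)
        rng = np.random.default_rng(0)
        y = rng.normal(size=small_locus.n_samples)
        y = y - y.mean()
        y = y - U @ (U.T @ y)  # construct phenotype orthogonal to PCs, mean zero
        out = fs.residualize(small_locus, y, n_pcs=5)
        np.testing.assert_allclose(out.values, y, atol=1e-10)

    def test_pc1_phenotype_zeroed(self, small_locus):
        U = _genotype_pcs(small_locus.dosages, 1, scale=False)
        out = fs.residualize(small_locus, U[:, 0], n_pcs=5)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_pcs(self, small_locus):
        y = np.random.default_rng(1).normal(size=small_locus.n_samples)
        out = fs.residualize(small_locus, y, n_pcs=5)
        U = _genotype_pcs(small_locus.dosages, 5, scale=False)
        assert np.all(np.abs(U.T @ out.values) < 1e-8)
        assert out.residualized and out.n_pcs_removed == 5

    def test_idempotent(self, small_locus):
        y = np.random.default_rng(2).normal(size=small_locus.n_samples)
        once = fs.residualize(small_locus, y, n_pcs=5)
        twice = fs.residualize(small_locus, once, n_pcs=5)
        assert np.max(np.abs(twice.values - once.values)) < 1e-10

    def test_estimator_matches_function(self, small_locus):
        y = np.random.default_rng(3).normal(size=small_locus.n_samples)
        est = fs.PCResidualizer(n_pcs=5).fit(small_locus)
        np.testing.assert_allclose(
            est.transform(y), fs.residualize(small_locus, y, 5).values, atol=1e-12
        )

    def test_elbow_utility(self):
        assert fs.choose_n_pcs_elbow([10.0, 9.5, 4.0, 3.8, 3.7]) == 2


class TestPlainSelect:
    def test_worked_example_pooled_vector(self, worked_example):
        result = fs.FineMapResult(
            pooled=worked_example["pooled"],
            variant_ids=worked_example["variant_ids"],
            positions=np.arange(1, 6),
        )
        outcome = fs.plain_select(result)
        assert outcome.selections[0].variant_id == "A1"
        assert outcome.selections[0].pooled_prob == pytest.approx(0.45)

    def test_single_support(self):
        vec = PosteriorVector(support=[3], probs=[1.0], lead_index=3)
        result = fs.FineMapResult(
            pooled=[vec], variant_ids=[f"v{i}" for i in range(5)],
            positions=np.arange(5),
        )
        assert fs.plain_select(result).selections[0].variant_id == "v3"

    def test_matches_brute_force_argmax(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            vec = random_sparse_vector(rng, 20)
            result = fs.FineMapResult(
                pooled=[vec], variant_ids=[f"v{i:02d}" for i in range(20)],
                positions=np.arange(20),
            )
            pick = fs.plain_select(result).selections[0]
            assert pick.variant_index == vec.support[np.argmax(vec.probs)]


class TestStableRule:
    def test_worked_example(self, worked_example):
        picks = fs.stable_from_vectors(
            worked_example["pooled"],
            worked_example["slices"],
            worked_example["variant_ids"],
        )
        sel = picks[0]
        assert sel.variant_id == "A2"
        assert sel.pooled_prob == pytest.approx(0.43)
        assert sel.support_count == 3  # pooled + both slices

    def test_worked_example_stable_set(self, worked_example):
        # recompute the candidate set by hand: A2 and A4 appear in all 3 vectors
        pooled = worked_example["pooled"][0]
        counts = {}
        vecs = [pooled] + [v[0] for v in worked_example["slices"].values()]
        for i in pooled.support[pooled.probs > 0]:
            counts[i] = sum(v.prob_of(i) > 0 for v in vecs)
        best = max(counts.values())
        stable_set = {worked_example["variant_ids"][i] for i, c in counts.items() if c == best}
        assert stable_set == {"A2", "A4"}

    def test_slice_equal_to_pooled_reduces_to_plain(self, worked_example):
        pooled = worked_example["pooled"]
        picks = fs.stable_from_vectors(
            pooled, {"E1": pooled}, worked_example["variant_ids"]
        )
        result = fs.FineMapResult(
            pooled=pooled, variant_ids=worked_example["variant_ids"],
            positions=np.arange(1, 6),
        )
        assert picks[0].variant_id == fs.plain_select(result).selections[0].variant_id

    def test_matches_brute_force_two_stage_filter(self):
        rng = np.random.default_rng(17)
        ids = np.asarray([f"v{i:02d}" for i in range(15)], dtype=object)
        positions = np.arange(1, 16)
        for _ in range(100):
            pooled = [random_sparse_vector(rng, 15)]
            slices = {
                "s1": [random_sparse_vector(rng, 15)],
                "s2": [random_sparse_vector(rng, 15)],
            }
            pick = fs.stable_from_vectors(pooled, slices, ids, positions)[0]
            # oracle: enumerate candidates and counts explicitly
            vecs = [pooled[0], slices["s1"][0], slices["s2"][0]]
            cands = [int(i) for i in pooled[0].support if pooled[0].prob_of(i) > 0]
            counts = {i: sum(v.prob_of(i) > 0 for v in vecs) for i in cands}
            best = max(counts.values())
            finalists = [i for i in cands if counts[i] == best]
            # max pooled prob, ties by position then id
            finalists.sort(key=lambda i: (-pooled[0].prob_of(i), positions[i], ids[i]))
            assert pick.variant_index == finalists[0]
            assert pick.support_count == best

    def test_stable_variant_in_pooled_support(self, worked_example):
        picks = fs.stable_from_vectors(
            worked_example["pooled"], worked_example["slices"],
            worked_example["variant_ids"],
        )
        assert picks[0].variant_index in worked_example["pooled"][0].support


class TestSupportFilter:
    def test_uniform_pips_all_retained(self):
        pips = np.full(8, 1 / 8)
        assert len(fs.susie_support_filter(pips, 8)) == 8  # boundary inclusive

    def test_threshold_arithmetic(self):
        pips = np.array([0.5, 0.3, 0.1, 0.05, 0.05])
        kept = fs.susie_support_filter(pips, 5)  # threshold 0.2
        assert list(kept) == [0, 1]

    def test_empty_support_gives_no_selection(self):
        vec = dense_vector([0.05, 0.1, 0.15], kind="pip")
        vec.probs = np.array([0.05, 0.05, 0.05])  # all below 1/3
        picks = fs.stable_from_vectors(
            [vec], {}, np.asarray(["a", "b", "c"], dtype=object)
        )
        assert picks == [None]


class TestBackends:
    def test_single_effect_recovers_causal(self, cohort_locus):
        phen = fs.simulate_phenotype(
            cohort_locus, fs.SimulationSpec(n_causal=1, phi=0.4, seed=5)
        )
        backend = fs.SingleEffectFineMapper(n_effects=1)
        vecs = backend.fine_map(cohort_locus, phen.values)
        top = vecs[0].support[np.argmax(vecs[0].probs)]
        causal = phen.causal_indices[0]
        # top PIP variant is the causal one or in strong LD with it
        r = np.corrcoef(
            cohort_locus.dosages[:, top], cohort_locus.dosages[:, causal]
        )[0, 1]
        assert top == causal or abs(r) > 0.5

    def test_pip_vectors_not_required_to_sum_to_one(self):
        vec = PosteriorVector(
            support=[0, 1], probs=[0.9, 0.8], lead_index=0, kind="pip", n_variants=2
        )
        assert vec.probs.sum() > 1  # no exception: PIP vectors are unnormalized

    def test_stable_select_with_susie_backend(self, small_locus):
        phen = fs.simulate_phenotype(
            small_locus, fs.SimulationSpec(n_causal=1, phi=0.4, seed=9)
        )
        outcome, result = fs.stable_select(
            small_locus, phen.values, backend="susie", seed=1, n_effects=2
        )
        assert outcome.method == "stable"
        assert len(outcome.selections) >= 1
        assert set(result.per_slice) == set(small_locus.populations)


class TestStrategyRelations:
    def test_top_with_zero_pcs_equals_plain(self, small_locus):
        phen = fs.simulate_phenotype(
            small_locus, fs.SimulationSpec(n_causal=1, phi=0.2, seed=3)
        )
        plain = fs.VariantSelector(
            method="plain", n_permutations=80, random_state=13
        ).fit(small_locus, phen.values)
        top, _ = fs.top_select(
            small_locus, phen.values, n_pcs=0, seed=13, n_permutations=80
        )
        assert [s.variant_id for s in top.selections] == [
            s.variant_id for s in plain.outcome_.selections
        ]

    def test_combined_with_zero_pcs_equals_stable(self, small_locus):
        phen = fs.simulate_phenotype(
            small_locus, fs.SimulationSpec(n_causal=1, phi=0.2, seed=4)
        )
        y_centered = phen.values - phen.values.mean()
        stable, _ = fs.stable_select(
            small_locus, y_centered, seed=21, n_permutations=80
        )
        combined, _ = fs.combined_select(
            small_locus, phen.values, n_pcs=0, seed=21, n_permutations=80
        )
        assert combined.method == "combined"
        assert [s.variant_id for s in combined.selections] == [
            s.variant_id for s in stable.selections
        ]

    def test_top_equals_plain_without_structure(self):
        # labels uninformative: all populations drawn from one distribution
        agree = 0
        for seed in range(20):
            gm = fs.synth_genotypes(
                n_per_pop=(40,) * 5, n_variants=30, ld_rho=0.6,
                fst_like_drift=0.0, seed=seed,
            )
            phen = fs.simulate_phenotype(
                gm, fs.SimulationSpec(n_causal=1, phi=0.4, seed=seed + 500)
            )
            plain = fs.VariantSelector(
                method="plain", n_permutations=60, n_potential_sets=1,
                random_state=seed,
            ).fit(gm, phen.values)
            top = fs.VariantSelector(
                method="top", n_permutations=60, n_potential_sets=1,
                random_state=seed,
            ).fit(gm, phen.values)
            if plain.outcome_.selections[0].variant_id == top.outcome_.selections[0].variant_id:
                agree += 1
        assert agree >= 18

    def test_method_tags_and_metadata(self, small_locus):
        phen = fs.simulate_phenotype(
            small_locus, fs.SimulationSpec(n_causal=1, phi=0.2, seed=6)
        )
        combined, _ = fs.combined_select(
            small_locus, phen.values, n_pcs=5, seed=2, n_permutations=50
        )
        assert combined.method == "combined"
        assert combined.n_pcs_removed == 5

    def test_small_slices_skipped_with_warning(self, small_locus):
        labels = np.asarray(small_locus.population_labels, dtype=object).copy()
        labels[:2] = "TINY"
        labels[2:] = "BULK"
        phen = fs.simulate_phenotype(
            small_locus, fs.SimulationSpec(n_causal=1, phi=0.3, seed=7)
        )
        with pytest.warns(UserWarning, match="TINY"):
            outcome, result = fs.stable_select(
                small_locus, phen.values, labels=labels, seed=3, n_permutations=40
            )
        assert "TINY" not in result.per_slice
        assert "BULK" in result.per_slice

    def test_selector_is_deterministic(self, small_locus):
        phen = fs.simulate_phenotype(
            small_locus, fs.SimulationSpec(n_causal=2, phi=0.2, seed=8)
        )
        runs = [
            fs.VariantSelector(
                method="stable", n_permutations=60, random_state=31
            ).fit(small_locus, phen.values).outcome_.to_frame()
            for _ in range(2)
        ]
        assert runs[0].equals(runs[1])
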