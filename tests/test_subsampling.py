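"""Biased-subsampling tests: covariance density, common/distinct draws, and
the subsample -> solve -> scatter cascade."""

import numpy as np
import pytest
from scipy import stats

from sgtcca.gtcca import StructureSpec, default_structures, solve, GtccaProblem
from sgtcca.subsampling import (
    CovarianceDensity,
    SubsampleScheme,
    biased_subsample,
    estimate_covariance_density,
    run_sgtcca,
)
from sgtcca.tensor_core import covariance_tensor, standardize


def three_view_blocks(rng, n=40, dims=(6, 5, 1)):
    blocks = [standardize(rng.standard_normal((n, d))) for d in dims[:-1]]
    blocks.append(standardize(rng.standard_normal((n, 1))))
    return blocks


class TestScheme:
    @pytest.mark.parametrize("kw", [
        dict(common_fraction=0.0),
        dict(distinct_fraction=1.0),
        dict(common_fraction=0.7, distinct_fraction=0.5),
        dict(n_subsamples=0),
        dict(density_subsample_fraction=0.0),
        dict(density_iterations=0),
        dict(bias_power=0.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SubsampleScheme(**kw)

    def test_density_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            CovarianceDensity([np.array([1.0, -0.5])])


class TestDensity:
    def test_exact_density_is_per_feature_entry_sum(self, rng):
        # fraction 1, one iteration, plain summation: density equals the
        # sum of tensor entries involving each feature over all structures
        blocks = three_view_blocks(rng)
        spec = default_structures(3, 2)
        scheme = SubsampleScheme(density_subsample_fraction=1.0,
                                 density_iterations=1, seed=0)
        dens = estimate_covariance_density(blocks, spec, scheme,
                                           standardize_structures=False)
        for v in range(2):
            oracle = np.zeros(blocks[v].n_features)
            for s in spec.structures:
                if v not in s:
                    continue
                t = covariance_tensor([blocks[u] for u in s], s).entries
                pos = s.index(v)
                axes = tuple(a for a in range(t.ndim) if a != pos)
                oracle += t.sum(axis=axes)
            np.testing.assert_allclose(dens.per_view[v], oracle, atol=1e-10)

    def test_phenotype_linked_feature_has_higher_density(self, rng):
        n = 200
        ph = rng.standard_normal(n)
        x = np.column_stack([ph + 0.05 * rng.standard_normal(n),
                             rng.standard_normal(n)])
        blocks = [standardize(x), standardize(ph.reshape(-1, 1))]
        spec = StructureSpec([(0, 1)])
        scheme = SubsampleScheme(density_subsample_fraction=1.0,
                                 density_iterations=1, seed=0)
        dens = estimate_covariance_density(blocks, spec, scheme)
        assert dens.per_view[0][0] > dens.per_view[0][1]

    def test_independent_features_have_similar_density(self, rng):
        blocks = [standardize(rng.standard_normal((2000, 6))),
                  standardize(rng.standard_normal((2000, 1)))]
        spec = StructureSpec([(0, 1)])
        scheme = SubsampleScheme(density_subsample_fraction=1.0,
                                 density_iterations=1, seed=0)
        dens = estimate_covariance_density(blocks, spec, scheme,
                                           standardize_structures=False)
        d = dens.per_view[0]
        assert d.std() / d.mean() < 1.0  # Monte-Carlo tolerance

    def test_deterministic_given_seed(self, rng):
        blocks = three_view_blocks(rng)
        spec = default_structures(3, 2)
        scheme = SubsampleScheme(density_subsample_fraction=0.5,
                                 density_iterations=4, seed=9)
        d1 = estimate_covariance_density(blocks, spec, scheme)
        d2 = estimate_covariance_density(blocks, spec, scheme)
        for a, b in zip(d1.per_view, d2.per_view):
            np.testing.assert_array_equal(a, b)

    def test_stratified_sweeps_observe_every_feature(self, rng):
        blocks = [standardize(rng.standard_normal((20, 10))),
                  standardize(rng.standard_normal((20, 1)))]
        spec = StructureSpec([(0, 1)])
        scheme = SubsampleScheme(density_subsample_fraction=0.2,
                                 density_iterations=5, seed=0)
        dens = estimate_covariance_density(blocks, spec, scheme)
        assert (dens.per_view[0] > 0).all()

    def test_rejects_empty_view_subsample(self, rng):
        blocks = three_view_blocks(rng)
        scheme = SubsampleScheme(density_subsample_fraction=0.01, seed=0)
        with pytest.raises(ValueError, match="no features"):
            estimate_covariance_density(blocks, default_structures(3, 2), scheme)


class TestBiasedSubsample:
    def test_sizes_match_rounded_fractions(self, rng):
        blocks = [standardize(rng.standard_normal((10, 50))),
                  standardize(rng.standard_normal((10, 1)))]
        dens = CovarianceDensity([np.ones(50), np.ones(1)])
        scheme = SubsampleScheme(common_fraction=0.1, distinct_fraction=0.04,
                                 n_subsamples=3, seed=0)
        common, distinct = biased_subsample(dens, scheme, blocks)
        assert len(common[0]) == 5
        assert all(len(d[0]) == 2 for d in distinct)
        # phenotype view fully included
        np.testing.assert_array_equal(common[1], [0])

    def test_paper_scale_sizes(self, rng):
        # p_c=0.08, p_d=0.02, d=1000 -> common 80, distinct 20, union 100
        blocks = [standardize(rng.standard_normal((5, 1000))),
                  standardize(rng.standard_normal((5, 1)))]
        dens = CovarianceDensity([np.ones(1000), np.ones(1)])
        scheme = SubsampleScheme(seed=1)
        common, distinct = biased_subsample(dens, scheme, blocks)
        assert len(common[0]) == 80
        assert len(distinct[0][0]) == 20
        union = np.union1d(common[0], distinct[0][0])
        assert len(union) == 100

    def test_dominant_density_feature_always_in_common(self, rng):
        blocks = [standardize(rng.standard_normal((10, 20))),
                  standardize(rng.standard_normal((10, 1)))]
        d = np.zeros(20)
        d[7] = 1.0
        scheme = SubsampleScheme(common_fraction=0.25, distinct_fraction=0.1,
                                 n_subsamples=2, seed=0)
        for seed in range(5):
            scheme.seed = seed
            common, _ = biased_subsample(
                CovarianceDensity([d, np.ones(1)]), scheme, blocks)
            assert 7 in common[0]

    def test_distinct_sets_exclude_common(self, rng):
        blocks = [standardize(rng.standard_normal((10, 30))),
                  standardize(rng.standard_normal((10, 1)))]
        dens = CovarianceDensity([rng.random(30) + 0.1, np.ones(1)])
        scheme = SubsampleScheme(common_fraction=0.2, distinct_fraction=0.1,
                                 n_subsamples=4, seed=2)
        common, distinct = biased_subsample(dens, scheme, blocks)
        for d in distinct:
            assert np.intersect1d(common[0], d[0]).size == 0

    def test_oversized_request_rejected(self, rng):
        blocks = [standardize(rng.standard_normal((10, 4))),
                  standardize(rng.standard_normal((10, 1)))]
        dens = CovarianceDensity([np.ones(4), np.ones(1)])
        scheme = SubsampleScheme(common_fraction=0.9, distinct_fraction=0.09)
        # 0.9*4 rounds to 4 and 0.09*4 rounds to 0 -> fine; push harder
        scheme2 = SubsampleScheme(common_fraction=0.8, distinct_fraction=0.2)
        object.__setattr__(scheme2, "common_fraction", 0.9)
        object.__setattr__(scheme2, "distinct_fraction", 0.4)
        with pytest.raises(ValueError, match="exceed"):
            biased_subsample(dens, scheme2, blocks)

    def test_inclusion_frequency_increases_with_density(self, rng):
        blocks = [standardize(rng.standard_normal((10, 40))),
                  standardize(rng.standard_normal((10, 1)))]
        density = np.linspace(0.5, 5.0, 40)
        counts = np.zeros(40)
        for seed in range(60):
            scheme = SubsampleScheme(common_fraction=0.25,
                                     distinct_fraction=0.1,
                                     n_subsamples=1, seed=seed)
            common, distinct = biased_subsample(
                CovarianceDensity([density, np.ones(1)]), scheme, blocks)
            counts[common[0]] += 1
            counts[distinct[0][0]] += 1
        rho, _ = stats.spearmanr(density, counts)
        assert rho > 0


class TestRunSgtcca:
    def test_subsampling_disabled_equals_full_solve(self, rng):
        blocks = three_view_blocks(rng, n=30, dims=(4, 3, 1))
        spec = default_structures(3, 2)
        scheme = SubsampleScheme(common_fraction=1.0, distinct_fraction=0.0,
                                 n_subsamples=1,
                                 density_subsample_fraction=1.0,
                                 density_iterations=1, seed=5)
        weights = run_sgtcca(blocks, spec, scheme, center_tensors=False,
                             scale_structures=False)
        tensors = {s: covariance_tensor([blocks[v].values for v in s], s).entries
                   for s in spec.structures}
        problem = GtccaProblem(tensors, [b.n_features for b in blocks], spec)
        direct = solve(problem, init="svd",
                       seed=np.random.default_rng(
                           np.random.SeedSequence(5 + 2).spawn(1)[0]))
        for j in range(3):
            np.testing.assert_allclose(weights.matrices[j][:, 0],
                                       direct.weights[j], atol=1e-12)

    def test_zero_pattern_matches_supports_and_unit_columns(self, rng):
        blocks = three_view_blocks(rng, n=25, dims=(12, 10, 1))
        spec = default_structures(3, 2)
        scheme = SubsampleScheme(common_fraction=0.3, distinct_fraction=0.2,
                                 n_subsamples=3,
                                 density_subsample_fraction=0.5,
                                 density_iterations=4, seed=3)
        weights = run_sgtcca(blocks, spec, scheme)
        for i in range(3):
            for j in range(3):
                col = weights.matrices[j][:, i]
                support = np.flatnonzero(col != 0)
                np.testing.assert_array_equal(support, weights.supports[i][j])
                assert np.linalg.norm(col) == pytest.approx(1.0, abs=1e-8)

    def test_reproducible_given_seed(self, rng):
        blocks = three_view_blocks(rng, n=20, dims=(8, 6, 1))
        spec = default_structures(3, 2)
        scheme = SubsampleScheme(common_fraction=0.4, distinct_fraction=0.2,
                                 n_subsamples=2,
                                 density_subsample_fraction=0.5,
                                 density_iterations=3, seed=17)
        w1 = run_sgtcca(blocks, spec, scheme)
        w2 = run_sgtcca(blocks, spec, scheme)
        for a, b in zip(w1.matrices, w2.matrices):
            np.testing.assert_array_equal(a, b)

    def test_planted_signal_gets_larger_weights(self):
        # features 0..4 of each view share a latent factor with the
        # phenotype; their average |weight| across subsamples must exceed
        # that of pure-noise features
        rng = np.random.default_rng(7)
        n = 120
        latent = rng.standard_normal(n)
        omics = []
        for _ in range(2):
            x = rng.standard_normal((n, 20))
            x[:, :5] = latent[:, None] + 0.4 * rng.standard_normal((n, 5))
            omics.append(standardize(x))
        omics.append(standardize((latent + 0.5 * rng.standard_normal(n)).reshape(-1, 1)))
        spec = default_structures(3, 2)
        scheme = SubsampleScheme(common_fraction=0.25, distinct_fraction=0.15,
                                 n_subsamples=6,
                                 density_subsample_fraction=0.5,
                                 density_iterations=6, seed=0)
        weights = run_sgtcca(omics, spec, scheme)
        for j in range(2):
            mean_abs = np.abs(weights.matrices[j]).mean(axis=1)
            assert mean_abs[:5].mean() > mean_abs[5:].mean()

    def test_space_contract_subsample_dimensions(self, rng):
        blocks = three_view_blocks(rng, n=20, dims=(50, 40, 1))
        spec = default_structures(3, 2)
        scheme = SubsampleScheme(common_fraction=0.2, distinct_fraction=0.1,
                                 n_subsamples=2,
                                 density_subsample_fraction=0.5,
                                 density_iterations=2, seed=1)
        weights = run_sgtcca(blocks, spec, scheme)
        for i in range(2):
            for j, d in enumerate((50, 40)):
                expect = round(0.2 * d) + round(0.1 * d)
                assert len(weights.supports[i][j]) == expect
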