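"""Hierarchical covariance assembly, marginal likelihood and prediction."""

import numpy as np
import pytest

from hgptime import (
    HierarchySpec,
    KernelParams,
    ObservationSet,
    build_covariance,
    cross_covariance,
    log_marginal,
    log_marginal_grad,
    predict,
    rank_genes,
    variance_decomposition,
)
from hgptime.errors import StructureError

from conftest import (
    jittered,
    oracle_condition,
    oracle_cross_cov,
    oracle_mvn_logpdf,
    oracle_query_prior,
    oracle_two_layer_cov,
    random_two_layer_obs,
    random_two_layer_spec,
)

TWO_LAYER = HierarchySpec(
    layers=(("gene", KernelParams(1.0, 1.0)), ("replicate", KernelParams(0.5, 2.0))),
    noise_variance=0.1,
)


class TestBuildCovariance:
    def test_two_replicates_single_time(self):
        obs = ObservationSet(
            paths=[("g1", "r1"), ("g1", "r2")], times=[0.0, 0.0], values=[0.0, 0.0]
        )
        np.testing.assert_allclose(
            build_covariance(obs, TWO_LAYER), [[1.6, 1.0], [1.0, 1.6]], rtol=1e-14
        )

    def test_three_level_paths_diverge_above_replicate(self):
        # same gene, different experiments, equal times: only the root kernel couples them
        spec = HierarchySpec(
            layers=(
                ("gene", KernelParams(2.0, 0.5)),
                ("experiment", KernelParams(1.0, 1.0)),
                ("replicate", KernelParams(0.5, 2.0)),
            ),
            noise_variance=0.1,
        )
        obs = ObservationSet(
            paths=[("g1", "e1", "r1"), ("g1", "e2", "r1")], times=[3.0, 3.0], values=[0.0, 0.0]
        )
        S = build_covariance(obs, spec)
        assert S[0, 1] == pytest.approx(2.0, rel=1e-14)
        assert S[0, 0] == pytest.approx(2.0 + 1.0 + 0.5 + 0.1, rel=1e-14)

    def test_matches_block_assembly_oracle(self, rng):
        for _ in range(5):
            obs = random_two_layer_obs(rng).canonical()
            spec = random_two_layer_spec(rng)
            np.testing.assert_allclose(
                build_covariance(obs, spec), oracle_two_layer_cov(obs, spec), atol=1e-12
            )

    def test_symmetric_psd(self, rng):
        for _ in range(5):
            obs = random_two_layer_obs(rng)
            spec = random_two_layer_spec(rng)
            S = build_covariance(obs, spec)
            np.testing.assert_allclose(S, S.T, atol=1e-14)
            assert np.min(np.linalg.eigvalsh(S + 1e-8 * np.eye(len(S)))) >= -1e-10

    def test_marginal_consistency_under_record_deletion(self, rng):
        obs = random_two_layer_obs(rng, n_genes=1, n_reps=2, n_times=4).canonical()
        spec = random_two_layer_spec(rng)
        full = build_covariance(obs, spec)
        keep = [i for i in range(len(obs)) if i != 2]
        reduced = build_covariance(obs.take(keep), spec)
        np.testing.assert_allclose(reduced, full[np.ix_(keep, keep)], atol=1e-14)

    def test_single_replicate_reduces_to_plain_gp(self, rng):
        # one replicate: hierarchy covariance == plain GP with kernel k_g + k_f
        obs = random_two_layer_obs(rng, n_genes=1, n_reps=1, n_times=5).canonical()
        spec = random_two_layer_spec(rng)
        S = build_covariance(obs, spec)
        kg, kf = spec.layers[0][1], spec.layers[1][1]
        t = obs.times
        d2 = (t[:, None] - t[None, :]) ** 2
        plain = (
            kg.amplitude * np.exp(-kg.inv_lengthscale * d2)
            + kf.amplitude * np.exp(-kf.inv_lengthscale * d2)
            + spec.noise_variance * np.eye(len(t))
        )
        np.testing.assert_allclose(S, plain, atol=1e-13)

    def test_depth_mismatch_is_structural_error(self):
        obs = ObservationSet(paths=[("g1",)], times=[0.0], values=[1.0])
        spec = HierarchySpec(
            layers=(
                ("a", KernelParams(1, 1)),
                ("b", KernelParams(1, 1)),
                ("c", KernelParams(1, 1)),
            ),
            noise_variance=0.1,
        )
        with pytest.raises(StructureError):
            build_covariance(obs, spec)


class TestLogMarginal:
    def test_single_observation_closed_form(self):
        obs = ObservationSet(paths=[("g1", "r1")], times=[0.0], values=[0.0])
        v = 1.0 + 0.5 + 0.1
        assert log_marginal(obs, TWO_LAYER) == pytest.approx(
            -0.5 * np.log(2 * np.pi * v), rel=1e-6
        )

    def test_matches_generic_mvn_density(self, rng):
        for _ in range(5):
            obs = random_two_layer_obs(rng).canonical()
            spec = random_two_layer_spec(rng)
            expected = oracle_mvn_logpdf(
                obs.values, jittered(oracle_two_layer_cov(obs, spec), spec)
            )
            assert log_marginal(obs, spec) == pytest.approx(expected, abs=1e-8)

    def test_gaussian_scaling_identity(self, rng):
        obs = random_two_layer_obs(rng).canonical()
        spec = random_two_layer_spec(rng)
        c = 3.7
        scaled_spec = HierarchySpec(
            layers=tuple(
                (n, KernelParams(p.amplitude * c, p.inv_lengthscale)) for n, p in spec.layers
            ),
            noise_variance=spec.noise_variance * c,
        )
        scaled_obs = ObservationSet(
            paths=obs.paths, times=obs.times, values=obs.values * np.sqrt(c)
        )
        d = len(obs)
        assert log_marginal(scaled_obs, scaled_spec) == pytest.approx(
            log_marginal(obs, spec) - 0.5 * d * np.log(c), rel=1e-9
        )

    def test_gradient_matches_finite_differences(self, rng):
        obs = random_two_layer_obs(rng).canonical()
        spec = random_two_layer_spec(rng)
        _, grad = log_marginal_grad(obs, spec)
        v = spec.log_params()
        for i in range(v.size):
            e = np.zeros_like(v)
            e[i] = 1e-6
            fd = (
                log_marginal(obs, spec.with_log_params(v + e))
                - log_marginal(obs, spec.with_log_params(v - e))
            ) / 2e-6
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestCrossCovarianceAndPredict:
    def test_gene_level_lag_zero(self):
        obs = ObservationSet(paths=[("g1", "r1")], times=[2.0], values=[1.0])
        C = cross_covariance(obs, TWO_LAYER, "gene", ("g1",), [2.0])
        assert C[0, 0] == pytest.approx(1.0)  # k_g amplitude

    def test_other_replicate_lag_zero(self):
        obs = ObservationSet(paths=[("g1", "r1")], times=[2.0], values=[1.0])
        C = cross_covariance(obs, TWO_LAYER, "replicate", ("g1", "r2"), [2.0])
        assert C[0, 0] == pytest.approx(1.0)  # k_g only: different replicate
        C_same = cross_covariance(obs, TWO_LAYER, "replicate", ("g1", "r1"), [2.0])
        assert C_same[0, 0] == pytest.approx(1.5)  # k_g + k_f

    def test_matches_entrywise_oracle(self, rng):
        for _ in range(5):
            obs = random_two_layer_obs(rng).canonical()
            spec = random_two_layer_spec(rng)
            q = rng.uniform(0, 12, size=3)
            for level, gpath in [("gene", ("g0",)), ("replicate", ("g0", "r1"))]:
                np.testing.assert_allclose(
                    cross_covariance(obs, spec, level, gpath, q),
                    oracle_cross_cov(obs, spec, level, gpath, q),
                    atol=1e-12,
                )

    def test_unknown_level_is_structural_error(self, rng):
        obs = random_two_layer_obs(rng)
        with pytest.raises(StructureError):
            cross_covariance(obs, TWO_LAYER, "nope", ("g0",), [0.0])

    def test_prior_reversion_far_from_data(self, rng):
        obs = random_two_layer_obs(rng, n_genes=1)
        spec = random_two_layer_spec(rng)
        far = obs.times.max() + 10.0 / np.sqrt(min(p.inv_lengthscale for _, p in spec.layers))
        post = predict(obs, spec, "gene", ("g0",), [far])
        assert abs(post.mean[0]) < 1e-6 * np.sqrt(spec.total_amplitude)
        assert post.variance[0] == pytest.approx(spec.layers[0][1].amplitude, rel=1e-5)

    def test_noise_free_interpolation(self, rng):
        obs = random_two_layer_obs(rng, n_genes=1, n_reps=2, n_times=3).canonical()
        spec = HierarchySpec(
            layers=(("gene", KernelParams(1.0, 0.2)), ("replicate", KernelParams(0.4, 0.5))),
            noise_variance=1e-12,
        )
        i = 1
        post = predict(
            obs, spec, "replicate", obs.paths[i], [obs.times[i]]
        )
        assert post.mean[0] == pytest.approx(obs.values[i], abs=1e-4)

    def test_matches_joint_conditioning_oracle(self, rng):
        for _ in range(5):
            obs = random_two_layer_obs(rng).canonical()
            spec = random_two_layer_spec(rng)
            q = rng.uniform(0, 12, size=3)
            for level, gpath in [("gene", ("g1",)), ("replicate", ("g1", "r0"))]:
                post = predict(obs, spec, level, gpath, q)
                mean, cov = oracle_condition(
                    jittered(oracle_two_layer_cov(obs, spec), spec),
                    oracle_cross_cov(obs, spec, level, gpath, q),
                    oracle_query_prior(spec, level, q),
                    obs.values,
                )
                np.testing.assert_allclose(post.mean, mean, atol=1e-8)
                np.testing.assert_allclose(post.covariance, cov, atol=1e-8)

    def test_posterior_predictive_recovers_data_distribution(self, rng):
        # predicting the bottom layer at the training coordinates and adding
        # back beta*I must equal conditioning an independent-noise copy of
        # the data on the observed data (cov(y, y') = Sigma - beta*I)
        obs = random_two_layer_obs(rng, n_genes=1, n_reps=2, n_times=3).canonical()
        spec = random_two_layer_spec(rng)
        S = jittered(oracle_two_layer_cov(obs, spec), spec)
        C = S - spec.noise_variance * np.eye(len(obs))  # shared latents, independent noise
        mean, cov = oracle_condition(S, C, S, obs.values)
        # assemble the implementation's predictive per record (replicate level)
        pred_mean = np.empty(len(obs))
        for i in range(len(obs)):
            post = predict(obs, spec, "replicate", obs.paths[i], [obs.times[i]])
            pred_mean[i] = post.mean[0]
        np.testing.assert_allclose(pred_mean, mean, atol=1e-8)


class TestDiagnostics:
    def test_variance_decomposition_values(self):
        spec = HierarchySpec(
            layers=(("gene", KernelParams(8.7, 1.0)), ("replicate", KernelParams(0.6, 1.0))),
            noise_variance=0.7,
        )
        np.testing.assert_allclose(variance_decomposition(spec), [0.87, 0.06, 0.07], atol=1e-12)

    def test_variance_decomposition_sums_to_one(self, rng):
        for _ in range(5):
            spec = random_two_layer_spec(rng)
            assert variance_decomposition(spec).sum() == pytest.approx(1.0, abs=1e-15)
        single = HierarchySpec(layers=(("f", KernelParams(0.3, 1.0)),), noise_variance=0.3)
        np.testing.assert_allclose(variance_decomposition(single), [0.5, 0.5])

    def test_rank_genes_scores_and_ties(self):
        spec_a = HierarchySpec(
            layers=(("gene", KernelParams(8.7, 1.0)), ("replicate", KernelParams(0.6, 1.0))),
            noise_variance=0.7,
        )
        spec_b = HierarchySpec(
            layers=(("gene", KernelParams(1.0, 1.0)), ("replicate", KernelParams(1.0, 1.0))),
            noise_variance=1.0,
        )
        ranked = rank_genes({"B": spec_b, "A": spec_a})
        assert [g for g, _ in ranked] == ["A", "B"]
        assert ranked[0][1] == pytest.approx(8.7 / 1.3)
        # identical scores tie-break lexicographically by gene id
        tied = rank_genes({"z": spec_a, "a": spec_a, "m": spec_a})
        assert [g for g, _ in tied] == ["a", "m", "z"]

    def test_rank_genes_rejects_non_two_layer(self):
        single = HierarchySpec(layers=(("f", KernelParams(1, 1)),), noise_variance=0.1)
        with pytest.raises(StructureError):
            rank_genes({"A": single})
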