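"""PCA, membership functions, weights and D-value ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from saltscreen import (
    PipelineConfig,
    d_value_and_rank,
    evaluate,
    membership,
    pca_fit,
    standardize,
    stc_from_observations,
    weights,
)
from saltscreen.tolerance import ToleranceMatrix

from oracles import brute_force_eigh


def as_matrix(arr, traits=None):
    arr = np.asarray(arr, dtype=float)
    traits = traits or [f"t{j}" for j in range(arr.shape[1])]
    idx = [f"A{i:02d}" for i in range(arr.shape[0])]
    return ToleranceMatrix(pd.DataFrame(arr, index=idx, columns=traits), pd.DataFrame())


def random_matrix(rng, n, k):
    return as_matrix(rng.uniform(0.2, 1.1, size=(n, k)))


class TestStandardize:
    def test_zero_mean_unit_sd(self, default_stc):
        z, _, _ = standardize(default_stc)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_scale_invariance(self, default_stc):
        z1, _, _ = standardize(default_stc)
        scaled = ToleranceMatrix(default_stc.stc * 1000.0, pd.DataFrame())
        z2, _, _ = standardize(scaled)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)

    def test_constant_column_named_in_error(self):
        m = as_matrix([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]], traits=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            standardize(m)


class TestPcaFit:
    def test_two_trait_closed_form(self):
        """For two standardized traits with correlation r, eigenvalues are 1 +/- r."""
        rng = np.random.default_rng(0)
        for r_target in [0.8, 0.5, -0.3]:
            cov = np.array([[1.0, r_target], [1.0 * r_target, 1.0]])
            x = rng.multivariate_normal([0, 0], cov, size=4000)
            z, *_ = standardize(as_matrix(x))
            r_emp = np.corrcoef(z.to_numpy().T)[0, 1]
            model = pca_fit(z, PipelineConfig())
            np.testing.assert_allclose(
                model.eigenvalues, [1 + abs(r_emp), 1 - abs(r_emp)], atol=1e-10
            )

    def test_contribution_percentages(self):
        rng = np.random.default_rng(1)
        z, *_ = standardize(random_matrix(rng, 12, 5))
        model = pca_fit(z)
        assert model.contribution_pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(model.cumulative_pct) >= -1e-12).all()
        assert (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        z, *_ = standardize(random_matrix(rng, 10, 6))
        model = pca_fit(z)
        l = model.loadings.to_numpy()
        np.testing.assert_allclose(l.T @ l, np.eye(6), atol=1e-8)

    def test_fallback_retention_warns(self):
        # two weakly correlated traits: max eigenvalue 1 + |r| < threshold 1.5
        rng = np.random.default_rng(0)
        z, *_ = standardize(random_matrix(rng, 10, 2))
        with pytest.warns(UserWarning, match="retaining PC1"):
            model = pca_fit(z, PipelineConfig(eigenvalue_threshold=1.5))
        assert model.retained == [0]

    @pytest.mark.parametrize("seed", range(8))
    def test_eigen_oracle_agreement(self, seed):
        """Production eigenpairs match the charpoly + inverse-iteration oracle."""
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 8)
        k = rng.integers(2, min(n, 7))
        z, *_ = standardize(random_matrix(rng, int(n), int(k)))
        model = pca_fit(z)
        corr = z.to_numpy().T @ z.to_numpy() / (len(z) - 1)
        oracle_vals, oracle_vecs = brute_force_eigh(corr)
        np.testing.assert_allclose(model.eigenvalues, np.clip(oracle_vals, 0, None), atol=1e-8)
        # eigenvectors match up to sign
        prod = model.loadings.to_numpy()
        for j in range(prod.shape[1]):
            dot = abs(oracle_vecs[:, j] @ prod[:, j])
            assert dot == pytest.approx(1.0, abs=1e-7)
        # spectral reconstruction of the correlation matrix
        recon = (model.loadings.to_numpy() * model.eigenvalues) @ model.loadings.to_numpy().T
        np.testing.assert_allclose(recon, corr, atol=1e-8)


class TestMembershipWeightsD:
    def test_membership_hand_example(self):
        np.testing.assert_allclose(membership(np.array([2.0, 5.0, 8.0])), [0.0, 0.5, 1.0])

    def test_membership_degenerate_convention(self):
        np.testing.assert_allclose(membership(np.array([3.0, 3.0, 3.0])), 0.5)

    def test_membership_affine_invariance(self):
        f = np.array([0.3, -1.2, 2.0, 0.8])
        np.testing.assert_allclose(membership(f), membership(3.5 * f + 11.0), atol=1e-12)

    def test_weights_hand_example(self):
        class Model:
            contribution_pct = np.array([40.0, 30.0, 20.0, 10.0])
            retained = [0, 1, 2]
            scores = pd.DataFrame(columns=["PC1", "PC2", "PC3"])

        w = weights(Model())
        np.testing.assert_allclose(w, [4 / 9, 3 / 9, 2 / 9])

    def test_d_value_hand_example(self, default_stc):
        res = evaluate(default_stc)
        u = pd.DataFrame(
            {"PC1": [0.2, 0.4], "PC2": [0.4, 0.2]}, index=["A1", "A2"]
        )
        w = pd.Series([0.5, 0.5], index=["PC1", "PC2"])
        out = d_value_and_rank(u, w, res.model)
        np.testing.assert_allclose(out.d_value, [0.3, 0.3])
        assert list(out.rank) == [1, 1]

    def test_tie_ranks_share_minimum(self, default_stc):
        res = evaluate(default_stc)
        u = pd.DataFrame({"PC1": [1.0, 1.0, 0.0]}, index=["A1", "A2", "A3"])
        w = pd.Series([1.0], index=["PC1"])
        out = d_value_and_rank(u, w, res.model)
        assert list(out.rank) == [1, 1, 3]


class TestEvaluate:
    def test_two_identical_traits_three_accessions(self):
        """One retained component; D spreads (0, 0.5, 1) over the score order."""
        col = np.array([0.3, 0.6, 0.9])
        res = evaluate(as_matrix(np.column_stack([col, col])))
        assert len(res.model.retained) == 1
        np.testing.assert_allclose(np.sort(res.d_value.to_numpy()), [0.0, 0.5, 1.0], atol=1e-12)
        # higher STC -> more tolerant -> higher D
        assert res.d_value.iloc[2] == pytest.approx(1.0)

    def test_d_in_unit_interval_and_membership_extremes(self, default_stc):
        res = evaluate(default_stc)
        assert ((res.d_value >= 0) & (res.d_value <= 1)).all()
        u = res.membership
        assert (u.to_numpy() >= 0).all() and (u.to_numpy() <= 1).all()
        np.testing.assert_allclose(u.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(u.max(axis=0), 1.0, atol=1e-12)
        assert res.weights.sum() == pytest.approx(1.0)

    def test_permutation_invariance(self, default_stc):
        """Row/column permutations leave each accession's D value unchanged."""
        res = evaluate(default_stc)
        rng = np.random.default_rng(0)
        stc = default_stc.stc
        permuted = stc.iloc[
            rng.permutation(len(stc)), rng.permutation(stc.shape[1])
        ]
        res_p = evaluate(ToleranceMatrix(permuted, pd.DataFrame()))
        pd.testing.assert_series_equal(res.d_value, res_p.d_value, atol=1e-9, rtol=0)

    def test_noise_free_ranking_recovers_tau(self, noise_free_cohort):
        """After screening out the decoys, noise-off D ranking equals tau ranking."""
        from saltscreen import PipelineConfig, correlation_matrix, screen_traits

        _, obs, _, truth = noise_free_cohort
        tm = stc_from_observations(obs)
        rep = screen_traits(correlation_matrix(tm), PipelineConfig())
        res = evaluate(tm.subset(rep.retained))
        tau = pd.Series(truth.tau)[res.d_value.index]
        rho = spearmanr(tau, res.d_value).statistic
        assert rho == pytest.approx(1.0)

    def test_default_scenario_parameter_recovery(self, default_cohort, default_stc):
        _, _, _, truth = default_cohort
        res = evaluate(default_stc)
        tau = pd.Series(truth.tau)[res.d_value.index]
        assert spearmanr(tau, res.d_value).statistic >= 0.90
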