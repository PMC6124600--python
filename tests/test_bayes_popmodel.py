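"""The hierarchical allele-frequency model: Omega, XtX, Bayes factors."""

import numpy as np
import pandas as pd
import pytest

from divscan import simulate
from divscan.bayes_popmodel import (
    CovarianceMatrix,
    StandardizedEnv,
    _counts,
    canonicalize_omega,
    estimate_covariance,
    nearest_positive_definite,
    run_replicates,
    score_loci,
    score_locus,
    standardize_env,
)

from conftest import make_gm


def trait_frame(values, pops):
    return pd.DataFrame({"t": values}, index=pd.Index(pops, name="population"))


class TestStandardizeEnv:
    def test_hand_computed_values(self):
        env = standardize_env(trait_frame([1, 2, 3, 4], list("abcd")), "t", list("abcd"))
        np.testing.assert_allclose(
            env.values, [-1.1619, -0.3873, 0.3873, 1.1619], atol=1e-4
        )

    def test_mean_zero_sd_one(self):
        env = standardize_env(
            trait_frame([0.31, 0.24, 0.32, 0.33], list("abcd")), "t", list("abcd")
        )
        assert env.values.mean() == pytest.approx(0, abs=1e-12)
        assert env.values.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_constant_trait_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize_env(trait_frame([2, 2, 2], list("abc")), "t", list("abc"))

    def test_env_invariant_enforced(self):
        with pytest.raises(ValueError, match="standardized"):
            StandardizedEnv("t", np.array([0.0, 1.0]), ["a", "b"])


class TestCovarianceMatrix:
    def test_symmetry_and_pd_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            CovarianceMatrix(np.array([[1, 0.5], [0.4, 1]]), ["a", "b"])
        with pytest.raises(ValueError, match="positive definite"):
            CovarianceMatrix(np.array([[1, 2], [2, 1]]), ["a", "b"])

    def test_text_roundtrip(self, tmp_path):
        om = CovarianceMatrix(0.1 * np.eye(3) + 0.02, list("abc"))
        om.to_text(tmp_path / "omega.txt")
        om2 = CovarianceMatrix.from_text(tmp_path / "omega.txt", list("abc"))
        np.testing.assert_allclose(om.omega, om2.omega, atol=1e-9)

    def test_nearest_pd_repair(self):
        m = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
        fixed = nearest_positive_definite(m)
        assert np.linalg.eigvalsh(fixed).min() > 0

    def test_canonicalization_restores_projected_identity(self):
        # the centering projection of F*I is the gauge image F*(I - J/K)
        for K in (2, 3, 4, 6):
            F = 0.1
            projected = F * (np.eye(K) - np.ones((K, K)) / K)
            np.testing.assert_allclose(
                canonicalize_omega(projected), F * np.eye(K), atol=1e-12
            )


@pytest.fixture(scope="module")
def omega4():
    return CovarianceMatrix(0.1 * np.eye(4), [f"pop{i}" for i in range(1, 5)])


@pytest.fixture(scope="module")
def env4(omega4):
    return standardize_env(trait_frame([1, 2, 3, 4], omega4.pops), "t", omega4.pops)


class TestScoring:

    def test_undifferentiated_below_fixed_difference(self, omega4):
        same = score_locus(
            np.array([8.0, 8, 8, 8]), np.array([20.0, 20, 20, 20]), omega4, seed=1
        )
        fixed = score_locus(
            np.array([20.0, 0, 0, 0]), np.array([20.0, 20, 20, 20]), omega4, seed=1
        )
        assert same.xtx < fixed.xtx
        assert same.xtx == pytest.approx(4, abs=2.0)  # near the null expectation K
        assert fixed.xtx > 8

    def test_xtx_nonnegative_and_deterministic(self, omega4):
        counts = np.array([[5.0, 10, 15, 8], [2.0, 2, 18, 18]])
        tot = np.full((2, 4), 20.0)
        a = score_loci(counts, tot, omega4, n_iter=400, seed=9)
        b = score_loci(counts, tot, omega4, n_iter=400, seed=9)
        assert (a["xtx"] >= 0).all()
        np.testing.assert_array_equal(a["xtx"], b["xtx"])

    def test_allele_swap_invariance(self, omega4):
        counts = np.array([[3.0, 10, 17, 9]])
        tot = np.full((1, 4), 20.0)
        a = score_loci(counts, tot, omega4, n_iter=20_000, seed=3)
        b = score_loci(tot - counts, tot, omega4, n_iter=20_000, seed=4)
        assert a["xtx"][0] == pytest.approx(b["xtx"][0], rel=0.1)

    def test_population_relabeling_invariance(self, omega4):
        counts = np.array([[3.0, 10, 17, 9]])
        tot = np.full((1, 4), 20.0)
        perm = [2, 0, 3, 1]
        om_p = CovarianceMatrix(
            omega4.omega[np.ix_(perm, perm)], [omega4.pops[i] for i in perm]
        )
        a = score_loci(counts, tot, omega4, n_iter=20_000, seed=5)
        b = score_loci(counts[:, perm], tot[:, perm], om_p, n_iter=20_000, seed=6)
        assert a["xtx"][0] == pytest.approx(b["xtx"][0], rel=0.1)

    def test_dimension_mismatch_is_error(self, omega4):
        with pytest.raises(ValueError, match="dimension"):
            score_loci(np.ones((1, 3)), np.full((1, 3), 10.0), omega4)

    def test_zero_variance_effect_prior_gives_bf_one(self, omega4, env4):
        env = env4
        st = score_locus(
            np.array([2.0, 6, 12, 18]), np.full(4, 20.0), omega4,
            env=env, beta_prior_sd=0.0, seed=2,
        )
        assert st.log10_bf == 0.0

    def test_bf_sign_tracks_collinearity(self, omega4, env4):
        env = env4
        collinear = score_locus(
            np.array([1.0, 6, 14, 19]), np.full(4, 20.0), omega4,
            env=env, mcmc_iterations=20_000, seed=7,
        )
        flat = score_locus(
            np.array([10.0, 10, 10, 10]), np.full(4, 20.0), omega4,
            env=env, mcmc_iterations=20_000, seed=8,
        )
        assert collinear.log10_bf > 0.5
        # an undifferentiated locus must not show positive evidence
        assert flat.log10_bf < 0.2
        assert flat.log10_bf < collinear.log10_bf


class TestReplicatesAndRecovery:
    def test_replicate_runs_need_two(self, neutral_sim):
        gm, _, _ = neutral_sim
        om = CovarianceMatrix(0.07 * np.eye(4), gm.pop_labels)
        with pytest.raises(ValueError, match="2 replicate"):
            run_replicates(gm, om, n_runs=1)

    def test_replicate_coherence(self, planted_sim):
        gm, _, _ = planted_sim
        om = CovarianceMatrix(0.07 * np.eye(4), gm.pop_labels)
        tab = run_replicates(gm, om, n_runs=2, n_iter=500, seed=31)
        from scipy.stats import spearmanr

        rho = spearmanr(tab.scores[:, 0], tab.scores[:, 1]).statistic
        assert rho > 0.3

    def test_duplicated_populations_have_matching_rows(self):
        rng = np.random.default_rng(17)
        L, n = 600, 10
        p_anc = rng.uniform(0.1, 0.9, L)
        F = 0.1
        p_pop = rng.beta(
            (p_anc * (1 - F) / F)[:, None], ((1 - p_anc) * (1 - F) / F)[:, None],
            (L, 3),
        )
        dup = np.column_stack([p_pop, p_pop[:, 0]])  # pop4 duplicates pop1
        dosage = rng.binomial(2, np.repeat(dup, n, axis=1)).astype(np.int8)
        gm = make_gm(
            dosage,
            pops=[p for p in ("A", "B", "C", "D") for _ in range(n)],
            positions=(np.arange(L) + 1) * 50,
        )
        om = estimate_covariance(gm, n_subsets=1, subset_size=L, n_iter=1200, seed=23)
        # genotypes in A and D are conditionally i.i.d. given shared p -> high cov
        cov_ad = om.omega[0, 3]
        others = [om.omega[0, 1], om.omega[0, 2], om.omega[1, 3], om.omega[2, 3]]
        assert cov_ad > max(others) + 0.02
        assert om.omega[0, 0] == pytest.approx(om.omega[3, 3], abs=0.05)

    def test_subset_larger_than_dataset_uses_all(self, neutral_sim):
        gm, _, _ = neutral_sim
        om = estimate_covariance(gm, n_subsets=1, subset_size=10**6, n_iter=300, seed=3)
        assert om.provenance["subset_size"] == gm.n_loci
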