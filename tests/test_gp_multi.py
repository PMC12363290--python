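"""Multi-environment models: balance detection, Hadamard/Kronecker covariances,
environment-covariance estimation, and the two Gibbs samplers."""

import numpy as np
import pandas as pd
import pytest

from hybridgp import MCMCSettings, SingleEnvModelSpec, fit_single_env
from hybridgp.gp_multi import (
    MultiEnvModelSpec,
    build_hadamard_covariance,
    detect_balance,
    estimate_E,
    fit_multi_env,
)
from hybridgp.phenotypes import PhenotypeTable
from hybridgp.relation_kernels import RelationshipKernel
from hybridgp import synthetic_data as sd

from conftest import random_psd

FAST = MCMCSettings(n_iter=3000, burn_in=500, thin=5, seed=1)


def _table(cells):
    return PhenotypeTable(
        pd.DataFrame(cells, columns=["genotype", "environment", "value"])
    )


class TestDetectBalance:
    def test_complete_incidence_is_balanced(self):
        cells = [(f"g{i}", e, 0.1 * i) for i in range(10) for e in ("e1", "e2", "e3")]
        label, summary = detect_balance(_table(cells))
        assert label == "balanced"
        assert summary["per_env_counts"] == {"e1": 10, "e2": 10, "e3": 10}
        np.testing.assert_array_equal(
            np.diag(summary["overlap"].to_numpy()), [10, 10, 10]
        )

    def test_one_missing_cell_is_unbalanced(self):
        cells = [(f"g{i}", e, 0.0) for i in range(10) for e in ("e1", "e2")]
        cells.pop()
        label, _ = detect_balance(_table(cells))
        assert label == "unbalanced"

    def test_single_environment_rejected(self):
        with pytest.raises(ValueError, match="2 environments"):
            detect_balance(_table([("g1", "e1", 0.0), ("g2", "e1", 1.0)]))


class TestHadamardCovariance:
    def _setup(self, rng, n=4, m=2):
        K = random_psd(rng, n)
        ids = [f"g{i}" for i in range(n)]
        envs = [f"e{j}" for j in range(m)]
        kern = RelationshipKernel(ids=ids, matrix=K)
        cells = [(g, e, 0.0) for e in envs for g in ids]
        U = random_psd(rng, m, unit_mean_diag=False)
        E = pd.DataFrame(U, index=envs, columns=envs)
        return kern, _table(cells), E, K, U

    def test_balanced_incidence_matches_kronecker(self, rng):
        for n, m in [(2, 2), (3, 3), (5, 2), (4, 3)]:
            kern, ph, E, K, U = self._setup(rng, n, m)
            H = build_hadamard_covariance(kern, ph, E)
            np.testing.assert_allclose(H, np.kron(U, K), atol=1e-12)

    def test_all_ones_E_gives_shared_main_effect(self, rng):
        kern, ph, E, K, _ = self._setup(rng, 3, 2)
        E[:] = 1.0
        H = build_hadamard_covariance(kern, ph, E)
        np.testing.assert_allclose(H, np.tile(K, (2, 2)), atol=1e-12)

    def test_identity_E_gives_block_diagonal(self, rng):
        kern, ph, E, K, _ = self._setup(rng, 3, 2)
        E[:] = np.eye(2)
        H = build_hadamard_covariance(kern, ph, E)
        np.testing.assert_allclose(H[:3, 3:], 0.0, atol=1e-12)
        np.testing.assert_allclose(H[:3, :3], K, atol=1e-12)

    def test_missing_environment_in_E(self, rng):
        kern, ph, E, *_ = self._setup(rng, 3, 2)
        with pytest.raises(KeyError, match="absent"):
            build_hadamard_covariance(kern, ph, E.iloc[:1, :1])


class TestEstimateE:
    def test_identical_phenotypes_give_unit_correlation(self):
        vals = np.arange(10.0)
        cells = [(f"g{i}", e, vals[i]) for i in range(10) for e in ("e1", "e2")]
        E = estimate_E(_table(cells), shrink=0.0)
        assert E.loc["e1", "e2"] == pytest.approx(1.0)

    def test_independent_phenotypes_near_zero(self):
        rng = np.random.default_rng(2)
        cells = [
            (f"g{i}", e, rng.standard_normal()) for i in range(1000) for e in ("a", "b")
        ]
        E = estimate_E(_table(cells), shrink=0.0)
        assert abs(E.loc["a", "b"]) < 0.1

    def test_full_shrink_gives_compound_symmetry(self):
        rng = np.random.default_rng(3)
        cells = [
            (f"g{i}", e, rng.standard_normal())
            for i in range(20)
            for e in ("a", "b", "c")
        ]
        E = estimate_E(_table(cells), shrink=1.0).to_numpy()
        off = E[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])
        np.testing.assert_allclose(np.diag(E), 1.0)

    def test_insufficient_overlap_warns_and_fills(self):
        rng = np.random.default_rng(4)
        cells = [(f"g{i}", "a", rng.standard_normal()) for i in range(10)]
        cells += [(f"g{i}", "b", rng.standard_normal()) for i in range(10)]
        cells += [(f"h{i}", "c", rng.standard_normal()) for i in range(10)]  # disjoint
        with pytest.warns(UserWarning, match="overlap"):
            E = estimate_E(_table(cells), shrink=0.0)
        assert np.isfinite(E.to_numpy()).all()


class TestFitMultiEnv:
    def test_balanced_recovery_of_U_and_R_diagonals(self, small_study):
        K = small_study["kernels"]["K"]
        m = 3
        U = {"K": 0.6 * ((1 - 0.5) * np.eye(m) + 0.5)}
        R = 0.3 * np.eye(m)
        tab, _ = sd.simulate_phenotypes_multi(
            {"K": K}, U, R, [f"e{j}" for j in range(m)], seed=9
        )
        spec = MultiEnvModelSpec(
            kernel_set=("K",), mcmc=MCMCSettings(4000, 1000, 5, seed=10)
        )
        fit = fit_multi_env(tab, [K], spec)
        assert fit.mode == "balanced_kron"
        for j in range(m):
            mu_, sd_ = fit.U_posterior["K"][0][j, j], fit.U_posterior["K"][1][j, j]
            assert abs(mu_ - 0.6) < 3 * sd_ + 0.05
            mr, sr = fit.R_posterior[0][j, j], fit.R_posterior[1][j, j]
            assert abs(mr - 0.3) < 3 * sr + 0.05

    def test_unbalanced_mode_selected_and_fits(self, small_study):
        K = small_study["kernels"]["K"]
        m = 3
        U = {"K": 0.6 * ((1 - 0.5) * np.eye(m) + 0.5)}
        tab, _ = sd.simulate_phenotypes_multi(
            {"K": K}, U, 0.3 * np.eye(m), [f"e{j}" for j in range(m)], seed=11
        )
        sub = PhenotypeTable(tab.df.sample(frac=0.7, random_state=1))
        spec = MultiEnvModelSpec(kernel_set=("K",), mcmc=FAST)
        fit = fit_multi_env(sub, [K], spec)
        assert fit.mode == "unbalanced_hadamard"
        assert set(fit.varcomp_posterior) == {"K", "eps"}
        assert len(fit.yhat) == len(sub)

    def test_forced_balanced_mode_on_unbalanced_data_rejected(self, small_study):
        K = small_study["kernels"]["K"]
        cells = [(K.ids[i], e, 0.1 * i) for i in range(6) for e in ("e1", "e2")]
        cells.pop()
        spec = MultiEnvModelSpec(kernel_set=("K",), mode="balanced_kron", mcmc=FAST)
        with pytest.raises(ValueError, match="balanced_kron"):
            fit_multi_env(_table(cells), [K], spec)

    def test_m1_reduction_to_single_env(self, small_study):
        """One environment in the Hadamard machinery = the single-env model."""
        K = small_study["kernels"]["K"]
        y = small_study["y"]
        ph = PhenotypeTable.from_vector(K.ids, y)
        mc = MCMCSettings(5000, 1000, 5, seed=12)
        sfit = fit_single_env(
            y, [K], SingleEnvModelSpec(kernel_set=("K",), mcmc=mc)
        )
        E1 = pd.DataFrame([[1.0]], index=["env1"], columns=["env1"])
        mfit = fit_multi_env(
            ph,
            [K],
            MultiEnvModelSpec(
                kernel_set=("K",),
                mode="unbalanced_hadamard",
                env_cov_E=E1,
                mcmc=MCMCSettings(5000, 1000, 5, seed=13),
            ),
        )
        pairs = [("sigma2_K", "sigma2_K"), ("sigma2_eps", "sigma2_eps"), ("mu", "mu_env1")]
        for a, b in pairs:
            se = np.sqrt(sfit.mcse_of(a) ** 2 + mfit.mcse_of(b) ** 2)
            assert abs(sfit.chains[a].mean() - mfit.chains[b].mean()) < 3 * se

    def test_masked_environment_predicted_via_augmentation(self, small_study):
        K = small_study["kernels"]["K"]
        m = 2
        U = {"K": 0.6 * ((1 - 0.8) * np.eye(m) + 0.8)}
        tab, truths = sd.simulate_phenotypes_multi(
            {"K": K}, U, 0.2 * np.eye(m), ["e1", "e2"], seed=14
        )
        masked_cells = [(g, "e2") for g in K.ids[:60]]
        masked = tab.mask_cells(masked_cells)
        spec = MultiEnvModelSpec(kernel_set=("K",), mcmc=FAST)
        fit = fit_multi_env(masked, [K], spec)
        pred = fit.predict(masked_cells)
        truth = tab.df.set_index(["genotype", "environment"]).loc[
            [(g, "e2") for g in K.ids[:60]], "value"
        ].to_numpy()
        r = np.corrcoef(pred, truth)[0, 1]
        assert r > 0.3  # cross-env information flow recovers the masked cells

    def test_reproducibility(self, small_study):
        K = small_study["kernels"]["K"]
        m = 2
        tab, _ = sd.simulate_phenotypes_multi(
            {"K": K}, {"K": 0.5 * np.eye(m)}, 0.3 * np.eye(m), ["e1", "e2"], seed=15
        )
        spec = MultiEnvModelSpec(kernel_set=("K",), mcmc=FAST)
        f1 = fit_multi_env(tab, [K], spec)
        f2 = fit_multi_env(tab, [K], spec)
        for name in f1.chains:
            np.testing.assert_array_equal(f1.chains[name], f2.chains[name])
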