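import warnings

import numpy as np
import pytest

from hybridgp import synthetic_data as sd


@pytest.fixture(scope="session")
def small_study():
    """A small family-structured kernel set + S5-generated phenotypes."""
    cfg = sd.SimConfig(
        n_genotypes=120,
        n_markers=600,
        n_founders=10,
        generations=2,
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kernels, pedigree, markers = sd.simulate_kernel_set(cfg)
    y, truths = sd.simulate_phenotypes_single(
        kernels, cfg.variance_components, cfg.residual, seed=12
    )
    return {
        "config": cfg,
        "kernels": kernels,
        "pedigree": pedigree,
        "markers": markers,
        "y": y,
        "truths": truths,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_psd(rng: np.random.Generator, n: int, unit_mean_diag: bool = True):
    """Random symmetric PSD matrix, optionally scaled to mean diagonal 1."""
    B = rng.standard_normal((n, n + 2))
    M = B @ B.T / (n + 2)
    if unit_mean_diag:
        M = M / np.mean(np.diag(M))
    return M
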