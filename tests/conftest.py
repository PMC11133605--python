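import numpy as np
import pandas as pd
import pytest

from virtmet.config import SimulationConfig
from virtmet.instruments import HarmonizedInstrument


def make_instrument(gamma, se_x, Gamma, se_y, metabolite="metX", phenotype="008",
                    chrom=None) -> HarmonizedInstrument:
    """Build a harmonized instrument directly from effect arrays."""
    gamma = np.asarray(gamma, float)
    n = len(gamma)
    snps = pd.DataFrame({
        "variant": [f"rs{i + 1}" for i in range(n)],
        "chrom": chrom if chrom is not None else [str(i + 1) for i in range(n)],
        "pos": np.arange(1, n + 1) * 1_000_000,
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "beta_exp": gamma,
        "se_exp": np.asarray(se_x, float),
        "beta_out": np.asarray(Gamma, float),
        "se_out": np.asarray(se_y, float),
        "eaf_exp": np.full(n, 0.3),
        "eaf_out": np.full(n, 0.3),
    })
    return HarmonizedInstrument(metabolite, phenotype, snps)


def random_instrument(rng, n_snps, true_effect=0.25, n_exposure=50_000,
                      se_y=0.015, pleiotropy=None):
    """Summary-level instrument generator with known causal effect.

    Per-SNP exposure effects are drawn uniformly, measured with the SE a
    GWAS of ``n_exposure`` individuals would give; outcome effects are
    ``true_effect * gamma_true`` plus optional direct (pleiotropic)
    offsets, measured with SE ``se_y``.
    """
    g_true = rng.uniform(0.1, 0.3, n_snps) * rng.choice([-1.0, 1.0], n_snps)
    se_x = np.full(n_snps, 1.0 / np.sqrt(2 * 0.3 * 0.7 * n_exposure))
    gamma = g_true + rng.normal(0.0, se_x)
    alpha = np.zeros(n_snps) if pleiotropy is None else np.asarray(pleiotropy, float)
    se_y_arr = np.full(n_snps, se_y)
    Gamma = true_effect * g_true + alpha + rng.normal(0.0, se_y_arr)
    return make_instrument(gamma, se_x, Gamma, se_y_arr)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Scaled-down study used by fast integration tests."""
    return SimulationConfig(
        n_discovery=4000, n_exposure_gwas=2000, n_outcome_gwas=4000,
        n_metabolites=5, seed=7)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    from virtmet.synth import simulate_study

    return simulate_study(small_cfg)
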