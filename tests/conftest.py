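import numpy as np
import pytest
from scipy import stats

from near.inference import FitConfig, RibosomeTrafficModel
from near.model_core import GeneRates
from near.synthetic import MockSpec, end_to_end_fixture


def z_threshold(n_comparisons: int, df: int = 19, family_p: float = 0.0027) -> float:
    """Critical |z| for n simultaneous batch-means comparisons.

    The repo-wide agreement convention is "within 3 SE" per comparison
    (two-sided p = 0.0027 for a known SE).  Batch-means SEs are estimated from
    20 batches (Student-t, 19 df) and density tests scan many codons at once,
    so the per-comparison cutoff is Sidak-corrected to keep the family-wise
    false-alarm rate at the single-comparison 3-SE level.  A genuine bias
    grows like sqrt(sample time) and clears any such threshold.
    """
    p_each = 1.0 - (1.0 - family_p) ** (1.0 / max(n_comparisons, 1))
    return float(stats.t.ppf(1.0 - p_each / 2.0, df))


def random_small_instance(seed: int, L_max: int = 8):
    """A random small-lattice gene with exact-solver-sized state space."""
    rng = np.random.default_rng(seed)
    ell = int(rng.integers(1, 4))
    L = int(rng.integers(ell + 2, L_max + 1))
    k = rng.uniform(0.3, 3.0, L - 1)
    alpha = float(rng.uniform(0.2, 1.5))
    return GeneRates(f"rand{seed}", L, k, alpha=alpha, ell=ell)


@pytest.fixture(scope="session")
def dilute_gene():
    """Noise-free mock gene in the dilute regime plus its fitted model."""
    fx = end_to_end_fixture(
        MockSpec(gene_id="dilute", L=150, ell=10, kappa_low=100.0,
                 kappa_high=100.0, depth=None, seed=3)
    )
    res = RibosomeTrafficModel(fx.profile).fit(FitConfig(seed=11))
    return fx, res


@pytest.fixture(scope="session")
def congested_gene():
    """Noise-free mock gene with heavy traffic (kappa in [5, 50]) plus fit."""
    fx = end_to_end_fixture(
        MockSpec(gene_id="jam", L=150, ell=10, kappa_low=5.0,
                 kappa_high=50.0, depth=None, seed=4)
    )
    res = RibosomeTrafficModel(fx.profile).fit(FitConfig(seed=13))
    return fx, res
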