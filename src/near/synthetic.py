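"""Mock genes with known rates, for validation and testing without downloads.

The generator draws a transcript's intrinsic elongation-to-initiation ratios
from a log-uniform distribution (default kappa in [5, 50] on an L = 150,
ell = 10 lattice — an initiation-limited geometry with appreciable traffic),
simulates its stationary occupancy, samples read counts from the occupancy
(multinomially: reads conditionally independent given occupancy, with an
optional per-codon log-normal overdispersion hook), and normalizes them using
the simulation's own mean density as the "polysome profiling" value.  Ground
truth and observable are returned together, so parameter-recovery tests can
score the inference end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import DensityProfile, GeneRates
from .riboprof_io import NormalizedProfile, RawProfile, normalize
from .simulator import SimulatedDensities, SimulationConfig, simulate

__all__ = ["MockSpec", "Fixture", "generate_gene", "sample_reads", "end_to_end_fixture"]

_SEED_MOD = 2**31 - 1


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % _SEED_MOD for s in ss.generate_state(n)]


@dataclass
class MockSpec:
    """Recipe for one mock gene.

    ``alpha`` is the absolute initiation rate (1/s; 0.1/s is a typical yeast
    scale) and the elongation rates are ``k_i = kappa_i * alpha`` with
    ``kappa_i`` log-uniform in ``[kappa_low, kappa_high]``.  ``depth`` is the
    total A-site read count sampled onto the gene; ``depth=None`` marks the
    infinite-depth variant in which the simulated densities are used directly
    as the observable.  ``sim_time`` is the simulated sampling window in units
    of ``1/alpha``.
    """

    gene_id: str = "mock"
    L: int = 150
    ell: int = 10
    alpha: float = 0.1
    kappa_low: float = 5.0
    kappa_high: float = 50.0
    depth: int | None = 20_000
    overdispersion: float | None = None
    sim_time: float = 2e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0 < self.kappa_low <= self.kappa_high):
            raise ValueError("kappa bounds must be positive and ordered")


def generate_gene(spec: MockSpec) -> GeneRates:
    """Seeded, reproducible rate draw for one mock transcript."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    kappa = np.exp(
        rng.uniform(np.log(spec.kappa_low), np.log(spec.kappa_high), spec.L - 1)
    )
    return GeneRates(
        gene_id=spec.gene_id,
        L=spec.L,
        k=kappa * spec.alpha,
        alpha=spec.alpha,
        ell=spec.ell,
    )


def sample_reads(
    densities: DensityProfile,
    depth: int,
    seed: int = 0,
    overdispersion: float | None = None,
) -> RawProfile:
    """Multinomial read counts with ``p_i = rho_i / sum(rho)`` and ``sum = depth``.

    ``overdispersion`` (sigma of a per-codon log-normal multiplier on the
    sampling weights) lets robustness tests inject extra-Poisson noise.
    """
    rho = np.asarray(densities.rho, dtype=float)
    if rho.sum() <= 0:
        raise ValueError("cannot sample reads from an all-zero density profile")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w = rho.copy()
    if overdispersion is not None and overdispersion > 0:
        w = w * rng.lognormal(0.0, overdispersion, size=w.size)
    counts = rng.multinomial(depth, w / w.sum())
    return RawProfile(densities.gene_id, counts, densities.L)


@dataclass
class Fixture:
    """Ground truth and observable for one mock gene."""

    rates: GeneRates
    truth_kappa: np.ndarray
    sim: SimulatedDensities
    raw: RawProfile | None
    profile: NormalizedProfile

    def __iter__(self):
        # allows `rates, profile = end_to_end_fixture(spec)` unpacking
        return iter((self.rates, self.profile))


def end_to_end_fixture(spec: MockSpec) -> Fixture:
    """Chain generate -> simulate -> sample -> normalize for one mock gene.

    The simulation's mean density plays the role of the polysome-profiling
    measurement, so the normalized observable has the same mean density as the
    simulated truth.  With ``spec.depth is None`` the simulated densities are
    used directly as the (noise-free) observable.
    """
    seeds = _child_seeds(spec.seed, 2)
    rates = generate_gene(spec)
    sim = simulate(
        rates,
        SimulationConfig(seed=seeds[0], sample_time=spec.sim_time / spec.alpha),
    )
    truth_kappa = rates.k / rates.alpha
    if spec.depth is None:
        profile = NormalizedProfile(spec.gene_id, sim.profile.rho, ell=spec.ell)
        raw = None
    else:
        raw = sample_reads(
            sim.profile, spec.depth, seed=seeds[1], overdispersion=spec.overdispersion
        )
        profile = normalize(raw, sim.profile.rho_mean, ell=spec.ell)
    return Fixture(
        rates=rates, truth_kappa=truth_kappa, sim=sim, raw=raw, profile=profile
    )
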