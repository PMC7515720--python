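"""Analytic density approximations for the inhomogeneous ℓ-TASEP.

Two closed-form routes to the stationary densities are provided:

* :func:`ila_density` — the initiation-limited approximation (ILA), a
  systematic expansion of the stationary state in powers of the initiation
  rate.  Configurations with ``n`` ribosomes carry stationary weight of order
  ``alpha**n``; truncating at two-ribosome configurations and normalizing
  yields the density correct to second order in ``alpha``,

      rho_i = a_i + a^2-terms,   a_i = alpha / k_i = 1 / kappa_i,

  where the second-order terms (one-particle corrections ``b_i`` and
  two-particle weights ``c_ij``) follow from triangular recursions over the
  stationary balance equations (solved here by an O(L^2) dynamic program).
  The leading behaviour is ``rho_i ~ 1/kappa_i`` with a non-linear
  alpha-dependent correction; the truncation error is O(alpha^3).

* :func:`meanfield_density` / :func:`meanfield_invert` — the extended-particle
  mean-field closure in the MacDonald–Gibbs tradition.  The current through
  bond ``i`` is written with windowed occupancy sums,

      J = k_i rho_i (1 - sum_{j=i+1..i+ell} rho_j) / (1 - sum_{j=i+1..i+ell-1} rho_j),

  together with the initiation relation ``J = alpha (1 - sum_{2..ell+1} rho)``.
  The forward problem is solved by fixed-point iteration (backward sweeps);
  the inverse problem — kappa from an observed profile — is a direct
  evaluation of the same relations and is the starting point of the
  least-squares fit.

Both are functions of the ratios ``kappa_i = k_i / alpha`` only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model_core import DensityProfile, KappaProfile

__all__ = [
    "IlaOptions",
    "IlaValidityWarning",
    "MeanFieldConvergenceError",
    "ila_density",
    "meanfield_density",
    "meanfield_invert",
]

#: Truncation order of the small-alpha expansion implemented by ila_density.
ILA_ORDER = 2


class IlaValidityWarning(UserWarning):
    """Initiation is not clearly rate-limiting; the ILA may be inaccurate."""


class MeanFieldConvergenceError(RuntimeError):
    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"mean-field fixed point did not converge after {iterations} "
            f"iterations (residual {residual:.3e})"
        )


@dataclass
class IlaOptions:
    """Options for the initiation-limited approximation.

    ``validity_threshold``: minimum ``kappa_i`` below which a validity warning
    is emitted (default 1: elongation slower than initiation is outside the
    initiation-limited regime; a warning rather than an error because the
    downstream quality checks catch ILA breakdown explicitly).
    """

    validity_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not self.validity_threshold > 0:
            raise ValueError("validity_threshold must be > 0")


@njit(cache=True)
def _ila_second_order(kappa, ell):
    """Densities to O(alpha^2) for codons 2..L (alpha = 1, k = kappa)."""
    n = kappa.size  # L - 1
    L = n + 1
    a = 1.0 / kappa

    # two-ribosome stationary weights c[i, j] (codon indices, offset by 2)
    c = np.zeros((n, n))
    for i in range(2, L + 1):
        for j in range(i + ell, L + 1):
            denom = kappa[j - 2]
            if j >= i + ell + 1:
                denom += kappa[i - 2]
            inflow = 0.0
            if i == 2:
                inflow += a[j - 2]
            else:
                inflow += kappa[i - 3] * c[i - 3, j - 2]
            if j - 1 >= i + ell:
                inflow += kappa[j - 3] * c[i - 2, j - 3]
            c[i - 2, j - 2] = inflow / denom

    # one-ribosome O(alpha^2) corrections b_i
    b = np.zeros(n)
    kL = kappa[n - 1]
    if L >= 2 + ell:
        b[0] = kL * c[0, n - 1] / kappa[0]
    for i in range(3, L + 1):
        inflow = kappa[i - 3] * b[i - 3]
        if L >= i + ell:
            inflow += kL * c[i - 2, n - 1]
        if i >= ell + 2:
            inflow -= a[i - 2]
        b[i - 2] = inflow / kappa[i - 2]

    # normalize: rho_i = a_i + b_i + C_i - a_i * sum(a)  + O(alpha^3)
    A = a.sum()
    C = np.zeros(n)
    for i in range(n):
        for j in range(n):
            C[i] += c[i, j] + c[j, i]
    return a + b + C - a * A


def _kappa_array(kappa: KappaProfile | np.ndarray) -> np.ndarray:
    arr = kappa.kappa if isinstance(kappa, KappaProfile) else np.asarray(kappa, float)
    if not np.all(arr > 0):
        raise ValueError("all kappa_i must be > 0")
    return np.ascontiguousarray(arr, dtype=np.float64)


def ila_density(
    kappa: KappaProfile | np.ndarray,
    ell: int | None = None,
    options: IlaOptions | None = None,
) -> DensityProfile:
    """Initiation-limited densities ``rho_i^ILA({kappa_i})`` (source ``ILA``).

    Deterministic and smooth in each ``kappa_i`` (finite differences give
    usable derivatives for the optimizer).  Emits :class:`IlaValidityWarning`
    when ``min kappa_i`` falls below ``options.validity_threshold``.
    """
    opts = options or IlaOptions()
    if isinstance(kappa, KappaProfile):
        gene_id, ell_eff = kappa.gene_id, kappa.ell if ell is None else ell
    else:
        gene_id = ""
        if ell is None:
            raise ValueError("ell is required when kappa is a bare array")
        ell_eff = ell
    arr = _kappa_array(kappa)
    if arr.min() < opts.validity_threshold:
        warnings.warn(
            f"min kappa = {arr.min():.3g} < {opts.validity_threshold}: "
            "initiation is not rate-limiting, ILA may be invalid",
            IlaValidityWarning,
            stacklevel=2,
        )
    rho = _ila_second_order(arr, ell_eff)
    tie = 1.0 - rho[: ell_eff].sum()
    return DensityProfile(
        gene_id=gene_id, rho=rho, source="ILA", ell=ell_eff, J_over_alpha=tie
    )


def _windows(rho: np.ndarray, ell: int) -> tuple[np.ndarray, np.ndarray]:
    """Downstream occupancy sums over ell-1 and ell codons for each codon i.

    ``S1[i] = sum_{j=i+1..min(i+ell-1, L)} rho_j`` and ``Sl`` the same over
    ``ell`` codons; positions beyond the lattice are empty.
    """
    n = rho.size
    cs = np.concatenate(([0.0], np.cumsum(rho)))  # cs[m] = sum of first m entries
    idx = np.arange(n)
    hi1 = np.minimum(idx + ell - 1, n - 1)
    hil = np.minimum(idx + ell, n - 1)
    S1 = cs[hi1 + 1] - cs[idx + 1]
    Sl = cs[hil + 1] - cs[idx + 1]
    return S1, Sl


def meanfield_density(
    kappa: KappaProfile | np.ndarray,
    ell: int | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> DensityProfile:
    """Self-consistent mean-field densities (source ``MEANFIELD``).

    Fixed-point iteration over the windowed current–density relation for
    extended particles: each sweep recomputes ``J`` from the initiation
    relation and then updates ``rho_i = J (1 - S1_i) / (kappa_i (1 - Sl_i))``
    from the STOP codon upstream.  Converged when successive iterates differ
    by less than ``tol``; raises :class:`MeanFieldConvergenceError` (carrying
    the residual) otherwise.
    """
    if isinstance(kappa, KappaProfile):
        gene_id, ell_eff = kappa.gene_id, kappa.ell if ell is None else ell
    else:
        gene_id = ""
        if ell is None:
            raise ValueError("ell is required when kappa is a bare array")
        ell_eff = ell
    arr = _kappa_array(kappa)
    n = arr.size
    rho_max = 1.0 / ell_eff
    rho = np.minimum(1.0 / arr, 0.5 * rho_max)
    floor = 1e-12
    residual = np.inf
    # damped sweeps: undamped iteration can 2-cycle near the density ceiling
    omega = 0.5
    for _ in range(max_iter):
        J = max(1.0 - rho[:ell_eff].sum(), floor)
        new = rho.copy()
        for i in range(n - 1, -1, -1):
            hi1 = min(i + ell_eff - 1, n - 1)
            hil = min(i + ell_eff, n - 1)
            S1 = new[i + 1 : hi1 + 1].sum()
            Sl = new[i + 1 : hil + 1].sum()
            val = J * max(1.0 - S1, floor) / (arr[i] * max(1.0 - Sl, floor))
            new[i] = min(val, rho_max)
        residual = float(np.max(np.abs(new - rho)))
        rho = (1.0 - omega) * rho + omega * new
        if residual < tol:
            break
    else:
        raise MeanFieldConvergenceError(residual, max_iter)
    J = 1.0 - rho[:ell_eff].sum()
    return DensityProfile(
        gene_id=gene_id, rho=rho, source="MEANFIELD", ell=ell_eff, J_over_alpha=J
    )


def meanfield_invert(r, ell: int | None = None) -> KappaProfile:
    """Kappas for which the mean-field densities reproduce an observed profile.

    Direct evaluation of the mean-field relations at ``rho = r``:
    ``J = 1 - sum_{2..ell+1} r_i`` and
    ``kappa_i = J (1 - S1_i) / (r_i (1 - Sl_i))``.  The observed profile is
    a fixed point of :func:`meanfield_density` at these kappas, so the round
    trip reproduces ``r`` to solver tolerance.  Raises when any ``r_i`` lies
    outside ``(0, 1)`` (such genes are filtered upstream).
    """
    gene_id = getattr(r, "gene_id", "")
    if ell is None:
        ell = getattr(r, "ell", None)
        if ell is None:
            raise ValueError("ell is required when r carries no footprint size")
    arr = np.asarray(getattr(r, "r", r), dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("meanfield_invert requires 0 < r_i < 1 for all codons")
    floor = 1e-12
    J = max(1.0 - arr[:ell].sum(), floor)
    S1, Sl = _windows(arr, ell)
    kappa = J * np.maximum(1.0 - S1, floor) / (arr * np.maximum(1.0 - Sl, floor))
    return KappaProfile(gene_id=gene_id, kappa=kappa, ell=ell)
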