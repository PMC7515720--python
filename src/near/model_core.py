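"""Core domain types and an exact stationary-state solver for the ℓ-TASEP.

Translation of a single mRNA is modelled as a totally asymmetric simple
exclusion process with extended particles: ribosomes covering ``ell`` codons
hop unidirectionally along a lattice of ``L`` codons (codon 1 is START and
carries no density; profiles run over codons ``2..L``).  A ribosome is tracked
by its A-site position.  Initiation places an A-site on codon 2 at rate
``alpha`` provided codons ``2..ell+1`` hold no A-site; a ribosome at codon
``i`` advances at rate ``k_i`` provided the next downstream A-site is at least
``ell + 1`` codons away; from codon ``L`` it detaches at the termination rate
``k_L = beta``.

For small lattices the stationary master equation is a solvable linear system;
:func:`solve_stationary` enumerates every admissible A-site configuration,
assembles the sparse generator and solves for the stationary distribution.
This exact solution is the correctness oracle for the stochastic simulator and
the analytic approximations used at realistic gene sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "GeneRates",
    "KappaProfile",
    "LatticeState",
    "DensityProfile",
    "ExactSolution",
    "StateSpaceTooLarge",
    "enumerate_configurations",
    "solve_stationary",
    "exact_stationary",
    "DEFAULT_ELL",
    "DROPOFF_PROBABILITY_PER_CODON",
    "CHARACTERISTIC_ELONGATION_RATE",
    "estimated_dropoff_rate",
]

#: Default ribosome footprint in codons (~30 nt).
DEFAULT_ELL = 10

#: Probability of premature termination per translated codon (literature estimate).
DROPOFF_PROBABILITY_PER_CODON = 1e-4

#: Order-of-magnitude elongation rate in codons/s used for the drop-off estimate.
CHARACTERISTIC_ELONGATION_RATE = 10.0


def estimated_dropoff_rate(
    p_premature: float = DROPOFF_PROBABILITY_PER_CODON,
    elongation_rate: float = CHARACTERISTIC_ELONGATION_RATE,
) -> float:
    """Premature ribosome drop-off rate in 1/s.

    The product of the per-codon premature-termination probability (~1e-4) and
    a characteristic elongation rate (~10 codons/s) gives ~1e-3 1/s — orders of
    magnitude below typical elongation rates, which justifies neglecting
    drop-off in the model (the current J is then conserved along the
    transcript).
    """
    return p_premature * elongation_rate


class StateSpaceTooLarge(RuntimeError):
    """Raised when the exact solver's configuration count exceeds its cap."""

    def __init__(self, count: int, cap: int):
        self.count = count
        self.cap = cap
        super().__init__(
            f"state space too large: {count} admissible configurations "
            f"exceed the cap of {cap}"
        )


@dataclass
class GeneRates:
    """Absolute kinetic parameters of one transcript.

    Parameters
    ----------
    gene_id : str
        Transcript identifier.
    L : int
        Codon count including START (codon 1) and STOP (codon L).
    k : ndarray of shape (L - 1,)
        Elongation rates ``k_i`` (1/s) for codons ``i = 2..L``; the last entry
        ``k_L`` is the termination rate beta.
    alpha : float or None
        Initiation rate in 1/s.  May be ``None`` when only the ratios
        ``kappa_i = k_i / alpha`` are known.
    ell : int
        Ribosome footprint in codons.
    """

    gene_id: str
    L: int
    k: np.ndarray
    alpha: float | None = None
    ell: int = DEFAULT_ELL

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if self.L < self.ell + 1:
            raise ValueError(f"L={self.L} must be >= ell+1={self.ell + 1}")
        if self.k.shape != (self.L - 1,):
            raise ValueError(
                f"k must have length L-1={self.L - 1}, got {self.k.shape}"
            )
        if not np.all(self.k > 0):
            raise ValueError("all elongation/termination rates must be > 0")
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError("alpha must be > 0 when set")

    @property
    def beta(self) -> float:
        """Termination rate ``k_L``."""
        return float(self.k[-1])

    def rate_at(self, codon: int) -> float:
        """Rate ``k_i`` for codon ``i`` in ``2..L``."""
        return float(self.k[codon - 2])

    def to_kappa(self) -> "KappaProfile":
        """Relative rates ``kappa_i = k_i / alpha`` (requires ``alpha``)."""
        if self.alpha is None:
            raise ValueError("alpha is unset; cannot form kappa = k / alpha")
        return KappaProfile(self.gene_id, self.k / self.alpha, ell=self.ell)

    @classmethod
    def from_kappa(cls, kappa: "KappaProfile", alpha: float = 1.0) -> "GeneRates":
        """Absolute rates with ``alpha`` fixed; densities depend only on ratios."""
        return cls(
            gene_id=kappa.gene_id,
            L=kappa.L,
            k=alpha * kappa.kappa,
            alpha=alpha,
            ell=kappa.ell,
        )


@dataclass
class KappaProfile:
    """Elongation-to-initiation ratios ``kappa_i = k_i / alpha``, ``i = 2..L``.

    The only rate information recoverable from a density profile alone: the
    stationary densities of the exclusion process are invariant under a joint
    rescaling of ``alpha`` and all ``k_i``.  The last entry ``kappa_L`` is the
    termination-to-initiation ratio; ``kappa_over_kappaL`` (= ``k_i / k_L``)
    additionally removes the gene-specific initiation timescale.
    """

    gene_id: str
    kappa: np.ndarray
    ell: int = DEFAULT_ELL

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.kappa.ndim != 1 or self.kappa.size < 1:
            raise ValueError("kappa must be a 1-D array with length L-1 >= 1")
        if not np.all(self.kappa > 0):
            raise ValueError("all kappa_i must be > 0")

    @property
    def L(self) -> int:
        return self.kappa.size + 1

    @property
    def kappa_L(self) -> float:
        """Termination-to-initiation ratio."""
        return float(self.kappa[-1])

    @property
    def kappa_over_kappaL(self) -> np.ndarray:
        """``kappa_i / kappa_L = k_i / k_L``, invariant under rescaling alpha."""
        return self.kappa / self.kappa_L

    def codons(self) -> np.ndarray:
        return np.arange(2, self.L + 1)


@dataclass
class LatticeState:
    """One configuration C of A-sites plus its enabled transitions.

    ``a_sites`` is the ordered tuple of occupied A-site codons; ``moves`` lists
    the enabled transitions ``(label, target_codon_or_None, rate)`` — the
    off-diagonal rates W_{C->C'} of the master equation.
    """

    a_sites: tuple[int, ...]
    L: int
    ell: int
    moves: list[tuple[str, int | None, float]] = field(default_factory=list)

    @property
    def occupancy(self) -> np.ndarray:
        """Indicator tau_i over codons 2..L."""
        tau = np.zeros(self.L - 1, dtype=np.int8)
        for p in self.a_sites:
            tau[p - 2] = 1
        return tau

    def initiation_allowed(self) -> bool:
        return len(self.a_sites) == 0 or self.a_sites[0] > self.ell + 1

    def hop_allowed(self, m: int) -> bool:
        """Can the ``m``-th ribosome (upstream-to-downstream order) advance?"""
        i = self.a_sites[m]
        if i == self.L:
            return True  # termination needs no downstream clearance
        if m == len(self.a_sites) - 1:
            return True
        return self.a_sites[m + 1] >= i + self.ell + 1


@dataclass
class DensityProfile:
    """Model densities ``rho_i`` for codons ``2..L`` with provenance.

    ``source`` is one of ``{"ILA", "MEANFIELD", "SIMULATION", "EXACT"}``;
    ``J_over_alpha`` is the protein-production current divided by the
    initiation rate (equal to the translation initiation efficiency).
    """

    gene_id: str
    rho: np.ndarray
    source: str
    ell: int = DEFAULT_ELL
    J_over_alpha: float | None = None
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        if self.source not in {"ILA", "MEANFIELD", "SIMULATION", "EXACT"}:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def L(self) -> int:
        return self.rho.size + 1

    @property
    def rho_mean(self) -> float:
        """Mean density rho = sum(rho_i) / (L - 1), ribosomes/codon."""
        return float(self.rho.mean())

    @property
    def rho_max(self) -> float:
        """Maximum achievable density 1/ell."""
        return 1.0 / self.ell

    def codons(self) -> np.ndarray:
        return np.arange(2, self.L + 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "codon": self.codons(),
                "rho": self.rho,
                "se": self.se if self.se is not None else np.nan,
                "source": self.source,
            }
        )
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _iter_configurations(L: int, ell: int) -> Iterator[tuple[int, ...]]:
    """Yield all A-site arrangements on codons 2..L with spacing >= ell."""

    def extend(prefix: tuple[int, ...], start: int) -> Iterator[tuple[int, ...]]:
        yield prefix
        for pos in range(start, L + 1):
            yield from extend(prefix + (pos,), pos + ell)

    yield from extend((), 2)


def count_configurations(L: int, ell: int) -> int:
    """Number of A-site arrangements on codons 2..L with spacing >= ell."""
    # f[pos] = arrangements using only positions >= pos
    f = [1] * (L + ell + 2)
    for pos in range(L, 1, -1):
        f[pos] = f[pos + 1] + f[min(pos + ell, L + ell + 1)]
    return f[2]


def enumerate_configurations(
    L: int, ell: int, cap: int = 200_000
) -> list[LatticeState]:
    """Enumerate every admissible ribosome configuration on a lattice.

    Returns all arrangements of A-sites on codons ``2..L`` with pairwise
    spacing >= ``ell`` (including the empty lattice), each wrapped in a
    :class:`LatticeState`.  Raises :class:`StateSpaceTooLarge` when the count
    exceeds ``cap``.
    """
    total = count_configurations(L, ell)
    if total > cap:
        raise StateSpaceTooLarge(total, cap)
    return [LatticeState(c, L=L, ell=ell) for c in _iter_configurations(L, ell)]


@dataclass
class ExactSolution:
    """Full stationary solution of the master equation on a small lattice."""

    rates: GeneRates
    configs: list[tuple[int, ...]]
    P: np.ndarray  # stationary probabilities, same order as configs
    rho: np.ndarray  # <tau_i>, codons 2..L
    J: float  # k_L <tau_L>
    J_bonds: np.ndarray  # current through each bond i -> i+1 (and termination)
    J_init: float  # alpha * P(first ell codons free)
    conditional_clearance: np.ndarray  # P(i+1..i+ell free | A-site at i)

    @property
    def tie(self) -> float:
        """J / alpha = P(codons 2..ell+1 free of A-sites)."""
        return self.J_init / self.rates.alpha

    def to_profile(self) -> DensityProfile:
        return DensityProfile(
            gene_id=self.rates.gene_id,
            rho=self.rho,
            source="EXACT",
            ell=self.rates.ell,
            J_over_alpha=self.J / self.rates.alpha,
        )


def solve_stationary(rates: GeneRates, cap: int = 200_000) -> ExactSolution:
    """Solve the stationary master equation exactly on a small lattice.

    Enumerates the configuration space, assembles the sparse generator of the
    continuous-time Markov chain and solves for the stationary vector P*(C)
    (one balance equation replaced by normalization).  From P* it reports the
    densities ``rho_i = <tau_i>``, the current through every bond (identical
    across bonds when drop-off is neglected), the initiation current
    ``alpha * P(first ell codons free)`` and the per-codon conditional
    clearance probability that feeds the elongation-efficiency oracle.
    """
    if rates.alpha is None:
        raise ValueError("exact solver requires an absolute alpha (use 1.0 for ratios)")
    L, ell, alpha = rates.L, rates.ell, rates.alpha
    states = enumerate_configurations(L, ell, cap=cap)
    index = {s.a_sites: j for j, s in enumerate(states)}
    n = len(states)

    rows, cols, vals = [], [], []

    def add(src: int, dst: int, rate: float) -> None:
        rows.append(dst)
        cols.append(src)
        vals.append(rate)
        rows.append(src)
        cols.append(src)
        vals.append(-rate)

    for j, s in enumerate(states):
        c = s.a_sites
        if s.initiation_allowed():
            dst = index[(2,) + c]
            add(j, dst, alpha)
            s.moves.append(("init", 2, alpha))
        for m, i in enumerate(c):
            if not s.hop_allowed(m):
                continue
            rate = rates.rate_at(i)
            if i == L:
                nxt = c[:m] + c[m + 1 :]
                s.moves.append(("terminate", None, rate))
            else:
                nxt = c[:m] + (i + 1,) + c[m + 1 :]
                s.moves.append(("hop", i + 1, rate))
            add(j, index[nxt], rate)

    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # replace the last balance equation with sum(P) = 1
    A = Q.tolil()
    A[n - 1, :] = 1.0
    b = np.zeros(n)
    b[n - 1] = 1.0
    P = spla.spsolve(A.tocsr(), b)
    if not np.all(np.isfinite(P)):
        raise RuntimeError("stationary solve failed (non-finite solution)")
    P = np.maximum(P, 0.0)
    P /= P.sum()

    rho = np.zeros(L - 1)
    J_bonds = np.zeros(L - 1)
    clear_joint = np.zeros(L - 1)
    J_init = 0.0
    for j, s in enumerate(states):
        p = P[j]
        if p == 0.0:
            continue
        if s.initiation_allowed():
            J_init += alpha * p
        for m, i in enumerate(s.a_sites):
            rho[i - 2] += p
            if s.hop_allowed(m):
                clear_joint[i - 2] += p
                J_bonds[i - 2] += rates.rate_at(i) * p

    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(rho > 0, clear_joint / rho, np.nan)
    J = rates.beta * rho[-1]
    return ExactSolution(
        rates=rates,
        configs=[s.a_sites for s in states],
        P=P,
        rho=rho,
        J=J,
        J_bonds=J_bonds,
        J_init=J_init,
        conditional_clearance=cond,
    )


def exact_stationary(rates: GeneRates, cap: int = 200_000) -> DensityProfile:
    """Exact stationary densities (source ``EXACT``); see :func:`solve_stationary`."""
    return solve_stationary(rates, cap=cap).to_profile()
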