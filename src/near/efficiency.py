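"""Translation initiation and elongation efficiency scores.

Two dimensionless scores in [0, 1] quantify ribosome traffic and can be
compared across genes:

* TIE (translation initiation efficiency) — the current divided by the
  initiation rate, ``J/alpha = 1 - sum_{i=2..ell+1} rho_i``: the probability
  that the first ``ell`` codons are clear so an initiation attempt succeeds.
* TEE_i (translation elongation efficiency) — the ratio of intrinsic to total
  dwell time at codon ``i``, equivalently the probability that codons
  ``i+1..i+ell`` are clear given an A-site at ``i``; computed via the identity
  ``TEE_i = TIE / (kappa_i rho_i)``.

The per-codon extra dwell time due to blocking is
``alpha * t_i(collision) = r_i / TIE - 1 / kappa_i`` — zero exactly when the
codon sees no interference.  Scores for a fitted gene are computed from the
quality-check simulation (they are defined through occupancy probabilities,
which the analytic approximations only approximate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import DensityProfile, KappaProfile
from .riboprof_io import NormalizedProfile

__all__ = [
    "EfficiencyReport",
    "compute_tie",
    "compute_tee",
    "collision_time",
    "metagene_tee",
    "report_from_inference",
]


@dataclass
class EfficiencyReport:
    """Per-gene traffic scores; ``tee`` is NaN at rejected codons."""

    gene_id: str
    tie: float
    tee: np.ndarray
    alpha_t_coll: np.ndarray
    rho_over_rhomax: float
    status: np.ndarray | None = None

    @property
    def mean_tee(self) -> float:
        """Mean TEE over codons with an accepted estimate."""
        vals = self.tee[np.isfinite(self.tee)]
        return float(vals.mean()) if vals.size else np.nan

    @property
    def L(self) -> int:
        return self.tee.size + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_id,
                "codon": np.arange(2, self.L + 1),
                "tee": self.tee,
                "alpha_t_coll": self.alpha_t_coll,
            }
        )


def compute_tie(densities: DensityProfile, ell: int | None = None, tol: float = 1e-9) -> float:
    """TIE = 1 - sum of the first ``ell`` densities (= J/alpha).

    Raises if the result is negative beyond ``tol`` plus the profile's
    statistical error — an inconsistent profile.
    """
    ell_eff = densities.ell if ell is None else ell
    tie = 1.0 - float(densities.rho[:ell_eff].sum())
    slack = tol
    if densities.se is not None:
        slack += 3.0 * float(np.sqrt((densities.se[:ell_eff] ** 2).sum()))
    if tie < -slack:
        raise ValueError(f"inconsistent profile: TIE = {tie:.3g} < 0")
    return tie


def compute_tee(
    kappa: KappaProfile | np.ndarray,
    densities: DensityProfile,
    tie: float | None = None,
    clip: bool = True,
) -> np.ndarray:
    """Per-codon TEE via the identity ``TEE_i = TIE / (kappa_i rho_i)``.

    Codons with ``rho_i = 0`` are skipped (NaN).  Values outside [0, 1] —
    possible within simulation noise — are clipped when ``clip`` is set, with
    a warning counting the clipped codons.
    """
    k = kappa.kappa if isinstance(kappa, KappaProfile) else np.asarray(kappa, float)
    rho = densities.rho
    if tie is None:
        tie = compute_tie(densities)
    with np.errstate(divide="ignore", invalid="ignore"):
        tee = np.where(rho > 0, tie / (k * rho), np.nan)
    if clip:
        over = np.nansum(tee > 1.0)
        if over:
            warnings.warn(
                f"clipped {int(over)} TEE values above 1 (simulation noise)",
                stacklevel=2,
            )
        tee = np.clip(tee, 0.0, 1.0)
    return tee


def collision_time(
    r: NormalizedProfile | np.ndarray,
    tie: float,
    kappa: KappaProfile | np.ndarray,
    warn_negative: bool = True,
) -> np.ndarray:
    """Dimensionless traffic time ``alpha * t_i(collision) = r_i/TIE - 1/kappa_i``.

    Zero exactly at codons without ribosome interference; negative values are
    reported raw (they flag inconsistency between profile and rates) with a
    warning.
    """
    if not tie > 0:
        raise ValueError("tie must be > 0")
    r_arr = r.r if isinstance(r, NormalizedProfile) else np.asarray(r, float)
    k = kappa.kappa if isinstance(kappa, KappaProfile) else np.asarray(kappa, float)
    out = r_arr / tie - 1.0 / k
    if warn_negative and np.any(out < -1e-12):
        warnings.warn(
            f"{int(np.sum(out < -1e-12))} negative collision times "
            "(profile/rates inconsistency)",
            stacklevel=2,
        )
    return out


def report_from_inference(inference, profile: NormalizedProfile) -> EfficiencyReport:
    """Traffic scores for a fitted gene, from its quality-check simulation.

    TIE is the measured clear-window fraction of the backing run; TEE uses the
    identity with the final kappas and simulated densities, masked to accepted
    codons.
    """
    sim = inference.sim
    tie = sim.tie_measured
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tee = compute_tee(inference.kappa, sim.profile, tie=tie)
    tee = np.where(inference.accepted, tee, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coll = collision_time(profile, tie, inference.kappa, warn_negative=False)
    return EfficiencyReport(
        gene_id=profile.gene_id,
        tie=tie,
        tee=tee,
        alpha_t_coll=coll,
        rho_over_rhomax=profile.r_mean * profile.ell,
        status=inference.status,
    )


def metagene_tee(
    reports: list[EfficiencyReport],
    max_position: int | None = None,
    include_meanfield: bool = True,
) -> pd.DataFrame:
    """Median and quartile TEE per codon position across START-aligned genes.

    Each position aggregates the genes that have an accepted TEE there; genes
    shorter than a position simply drop out of it.  ``include_meanfield=False``
    additionally masks codons whose estimate came from the mean-field
    fallback.
    """
    if not reports:
        raise ValueError("need at least one report")
    from .inference import CodonStatus

    longest = max(r.L for r in reports)
    max_pos = longest if max_position is None else min(max_position, longest)
    rows = []
    for pos in range(2, max_pos + 1):
        vals = []
        for rep in reports:
            if pos > rep.L:
                continue
            v = rep.tee[pos - 2]
            if not np.isfinite(v):
                continue
            if (
                not include_meanfield
                and rep.status is not None
                and rep.status[pos - 2] == CodonStatus.ACCEPTED_MEANFIELD
            ):
                continue
            vals.append(v)
        if vals:
            arr = np.asarray(vals)
            rows.append(
                {
                    "codon": pos,
                    "median": float(np.median(arr)),
                    "q1": float(np.quantile(arr, 0.25)),
                    "q3": float(np.quantile(arr, 0.75)),
                    "n_genes": arr.size,
                }
            )
        else:
            rows.append(
                {"codon": pos, "median": np.nan, "q1": np.nan, "q3": np.nan, "n_genes": 0}
            )
    return pd.DataFrame(rows)
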