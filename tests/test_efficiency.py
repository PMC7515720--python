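"""TIE/TEE formulas against the exact solver and metagene aggregation."""

import numpy as np
import pytest

from near.efficiency import (
    EfficiencyReport,
    collision_time,
    compute_tee,
    compute_tie,
    metagene_tee,
)
from near.model_core import DensityProfile, GeneRates, solve_stationary

from conftest import random_small_instance


class TestTie:
    def test_arithmetic(self):
        rho = np.zeros(10)
        rho[:3] = [0.1, 0.05, 0.05]  # first ell=3 codons sum to 0.2
        prof = DensityProfile("g", rho, source="EXACT", ell=3)
        assert compute_tie(prof) == pytest.approx(0.8)

    def test_empty_lattice(self):
        prof = DensityProfile("g", np.zeros(10), source="EXACT", ell=3)
        assert compute_tie(prof) == 1.0

    @pytest.mark.parametrize("seed", [0, 3, 5])
    def test_matches_current_identity_exactly(self, seed):
        gr = random_small_instance(seed)
        sol = solve_stationary(gr)
        tie = compute_tie(sol.to_profile())
        assert tie == pytest.approx(sol.J / gr.alpha, abs=1e-12)

    def test_inconsistent_profile_raises(self):
        rho = np.full(6, 0.5)  # first-3 sum = 1.5 > 1
        prof = DensityProfile("g", rho, source="EXACT", ell=3)
        with pytest.raises(ValueError, match="inconsistent"):
            compute_tie(prof)


class TestTee:
    def test_formula_arithmetic(self):
        rho = np.full(5, 0.1)
        prof = DensityProfile("g", rho, source="EXACT", ell=1)
        tee = compute_tee(np.full(5, 10.0), prof, tie=0.8)
        np.testing.assert_allclose(tee, 0.8)

    def test_dilute_limit_is_one(self):
        kappa = np.full(19, 1000.0)
        gr = GeneRates("g", 20, kappa, alpha=1.0, ell=3)
        sol = solve_stationary(gr)
        tee = compute_tee(kappa, sol.to_profile(), tie=sol.J / gr.alpha)
        assert np.all(tee[np.isfinite(tee)] > 0.99)

    @pytest.mark.parametrize("seed", [1, 2, 4])
    def test_equals_exact_conditional_clearance(self, seed):
        # TIE/(kappa_i rho_i) == P(next ell codons clear | A-site at i)
        gr = random_small_instance(seed)
        sol = solve_stationary(gr)
        kappa = gr.k / gr.alpha
        tee = compute_tee(kappa, sol.to_profile(), tie=sol.J / gr.alpha, clip=False)
        mask = np.isfinite(tee) & np.isfinite(sol.conditional_clearance)
        np.testing.assert_allclose(
            tee[mask], sol.conditional_clearance[mask], atol=1e-10
        )

    def test_zero_density_codons_skipped(self):
        rho = np.array([0.1, 0.0, 0.1])
        prof = DensityProfile("g", rho, source="EXACT", ell=1)
        tee = compute_tee(np.full(3, 5.0), prof, tie=0.9)
        assert np.isnan(tee[1]) and np.isfinite(tee[0])


class TestCollisionTime:
    def test_no_interference_boundary_is_exact_zero(self):
        # r_i/TIE == 1/kappa_i -> collision time exactly zero
        # (values chosen exactly representable in binary floating point)
        kappa = np.array([4.0, 8.0])
        tie = 0.5
        r = np.array([0.125, 0.0625])
        out = collision_time(r, tie, kappa, warn_negative=False)
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_worked_triple(self):
        out = collision_time(np.array([0.1]), 0.8, np.array([10.0]))
        assert out[0] == pytest.approx(0.025)

    def test_simulated_gene_nonnegative_within_noise(self, dilute_gene):
        fx, res = dilute_gene
        eff = res.efficiency()
        # collision times from a self-consistent simulated gene are >= -3 SE
        se = np.maximum(fx.sim.profile.se, 1e-5) / max(eff.tie, 1e-6)
        assert np.all(eff.alpha_t_coll > -3 * se - 1e-3)

    def test_requires_positive_tie(self):
        with pytest.raises(ValueError):
            collision_time(np.array([0.1]), 0.0, np.array([10.0]))


class TestMetagene:
    @staticmethod
    def _report(gene_id, tee):
        tee = np.asarray(tee, float)
        return EfficiencyReport(
            gene_id=gene_id,
            tie=0.9,
            tee=tee,
            alpha_t_coll=np.zeros_like(tee),
            rho_over_rhomax=0.1,
        )

    def test_identical_profiles_collapse(self):
        tee = np.linspace(0.8, 1.0, 20)
        meta = metagene_tee([self._report(f"g{i}", tee) for i in range(10)])
        np.testing.assert_allclose(meta["median"], tee)
        np.testing.assert_allclose(meta["q1"], meta["q3"])
        assert (meta["n_genes"] == 10).all()

    def test_short_gene_excluded_beyond_length(self):
        long = self._report("long", np.full(30, 0.9))
        short = self._report("short", np.full(10, 0.5))
        meta = metagene_tee([long, short])
        assert meta.loc[meta["codon"] == 5, "n_genes"].item() == 2
        assert meta.loc[meta["codon"] == 20, "n_genes"].item() == 1
        assert meta.loc[meta["codon"] == 20, "median"].item() == pytest.approx(0.9)

    def test_planted_elevated_start_recovered(self):
        rng = np.random.default_rng(0)
        reports = []
        for i in range(30):
            tee = 0.85 + 0.02 * rng.standard_normal(40)
            tee[:10] += 0.1  # codons 2-11 elevated by construction
            reports.append(self._report(f"g{i}", np.clip(tee, 0, 1)))
        meta = metagene_tee(reports)
        early = meta.loc[meta["codon"] <= 11, "median"].mean()
        late = meta.loc[meta["codon"] > 11, "median"].mean()
        assert early > late + 0.05

    def test_mean_tee_decreases_with_density_ladder(self):
        # rising initiation pressure (lower uniform kappa) lowers mean TEE
        from near.simulator import SimulationConfig, simulate

        mean_tees, densities = [], []
        for kappa, seed in [(60.0, 1), (25.0, 2), (12.0, 3)]:
            gr = GeneRates("g", 40, np.full(39, kappa), alpha=1.0, ell=3)
            sim = simulate(gr, SimulationConfig(seed=seed, sample_time=2e4))
            tee = compute_tee(
                gr.k, sim.profile, tie=sim.tie_measured
            )
            mean_tees.append(np.nanmean(tee))
            densities.append(sim.profile.rho_mean * gr.ell)
        assert densities[0] < densities[1] < densities[2]
        assert mean_tees[0] > mean_tees[1] > mean_tees[2]
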