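# near — non-equilibrium analysis of ribosome profiling

Ribo-seq gives a codon-resolution snapshot of where ribosomes sit on each
mRNA, but a high read density at a codon is ambiguous: the ribosome may be
slow at decoding it, or it may be stuck in a queue behind a downstream
ribosome. `near` resolves this ambiguity with an explicit traffic model of
translation and turns A-site density profiles into

* codon-specific **elongation-to-initiation ratios** κ<sub>i</sub> = k<sub>i</sub>/α
  — the *intrinsic* decoding rates, relative to initiation (absolute rates are
  not identifiable from density profiles: densities are invariant under a
  joint rescaling of all rates);
* **TIE** (translation initiation efficiency) = J/α ∈ [0, 1], the probability
  that the first ℓ codons are clear so an initiation attempt succeeds;
* **TEE<sub>i</sub>** (translation elongation efficiency) ∈ [0, 1], the
  probability that codons i+1…i+ℓ are clear given an A-site at i — i.e. the
  ratio of the actual to the intrinsic elongation rate at codon i;
* per-codon **collision times** α·t<sub>i</sub>(collision) = r<sub>i</sub>/TIE − 1/κ<sub>i</sub>.

It is aimed at quantitative translation researchers who have per-gene,
per-codon A-site counts (e.g. from a Riboviz-style pipeline) together with an
absolute ribosome density per mRNA from polysome profiling.

## Model

Translation is modelled as a totally asymmetric simple exclusion process with
extended particles (ℓ-TASEP): ribosomes covering ℓ = 10 codons hop along the
L codons of a transcript, tracked by their A-site. Initiation places an
A-site on codon 2 at rate α if codons 2…ℓ+1 are clear; a ribosome at codon i
advances at rate k_i if the next A-site is more than ℓ codons downstream;
termination from codon L occurs at rate k_L = β. In the stationary state the
current J = k_L⟨τ_L⟩ is conserved and J/α = 1 − Σ_{i=2..ℓ+1} ρ_i.

Fitting proceeds in four steps per gene:

1. counts are normalized so that the profile's mean equals the gene's
   absolute ribosome density: r_i = (c_i/Σc)·r̄·(L−1);
2. κ is estimated by least squares, S = Σ_i (ρ_i^ILA(κ) − r_i)², using an
   analytic initiation-limited expansion of the stationary density as the
   forward model, started from a mean-field inversion of the profile;
3. the fitted κ is handed to an exact stochastic (Gillespie) simulation;
4. each codon passes two checks: the analytic density must agree with the
   simulated one within 10% (else the mean-field κ_i is substituted and
   re-checked), and the simulated density must reproduce r_i within 5%.
   Codons failing either check are flagged, so every reported κ_i comes with
   an explicit reliability status.

## Worked example

Generate a mock gene with known rates in a heavy-traffic regime, fit it, and
inspect the result (all numbers below are actual program output):

```python
import numpy as np
from near import MockSpec, RibosomeTrafficModel, end_to_end_fixture
from near.inference import FitConfig

fx = end_to_end_fixture(MockSpec(gene_id="mock000", L=150, ell=10,
                                 kappa_low=5, kappa_high=50, depth=None, seed=4))
res = RibosomeTrafficModel(fx.profile).fit(FitConfig(seed=13))
print(res.summary())
```

```
Ribosome traffic model fit
==========================
gene:                 mock000
codons (2..L):        149
footprint ell:        10
mean density r:       0.0480 ribosomes/codon
objective S:          1.014e-03
accepted codons:      40.3%
  ACCEPTED_ILA: 10
  ACCEPTED_MEANFIELD: 50
  REJECTED_ILA_CHECK: 37
  REJECTED_FIT_CHECK: 52
TIE (J/alpha):        0.607
mean TEE (accepted):  0.930
rho/rho_max:          0.480
```

This gene carries 48% of the maximum possible ribosome density, so traffic is
heavy: only 40% of codons yield a trustworthy κ_i (mostly via the mean-field
fallback), initiation attempts fail 39% of the time (TIE = 0.61), and even
accepted codons lose ~7% of their speed to queuing (mean TEE = 0.93). Where
the estimates are accepted they are accurate:

```python
rel = np.abs(res.kappa - fx.truth_kappa) / fx.truth_kappa
acc = res.inference.accepted
print(f"median |kappa error| on accepted codons: {np.median(rel[acc]):.1%}")
# median |kappa error| on accepted codons: 1.4%
```

`res.to_frame()` gives the per-codon table (r, κ, κ/κ_L, status, check
errors); in a dilute gene (uniform κ = 100) the same pipeline accepts 100% of
codons with TIE ≈ 0.91 and mean TEE ≈ 0.999.

The same stages are available from the shell for TSV inputs:

```bash
near synth --spec mock.yaml --out-prefix mock     # mock cohort with truth
near asite --footprints fp.tsv --lengths len.tsv --out counts.tsv
near normalize --counts counts.tsv --densities polysome.tsv --out norm.tsv
near fit --profiles norm.tsv --config near.yaml --out fit.tsv
near efficiency --fit fit.tsv --out eff.tsv
near metagene --eff eff.tsv --out meta.tsv
near run --config near.yaml                       # all of the above + manifest
```

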