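# Methods

## Model

Translation of one mRNA is an inhomogeneous totally asymmetric simple
exclusion process with extended particles (ℓ-TASEP). Codons are 1-based;
codon 1 is START and carries no density; profiles cover i = 2…L with codon L
the STOP codon. A ribosome is represented by its A-site position; two A-sites
must be at least ℓ codons apart (default ℓ = 10, the ~30 nt footprint).
Moves and rates:

* initiation: ∅ → A-site at codon 2, rate α, allowed iff codons 2…ℓ+1 hold
  no A-site;
* elongation: i → i+1, rate k_i, allowed iff the next downstream A-site is at
  least i+ℓ+1 (equivalently codon i+ℓ is not covered);
* termination: detachment from codon L at rate k_L = β, with no downstream
  clearance requirement (the ribosome simply leaves).

Assumptions: no premature drop-off (the per-codon premature-termination
probability ~1e-4 times a ~10 codon/s elongation rate gives a drop-off rate
~1e-3 1/s, negligible against elongation, so the current J is conserved along
the transcript — `estimated_dropoff_rate` encodes this argument); no
re-initiation or mRNA circularization; the footprint enters only through
A-site spacing. Stationary densities depend on the rates only through the
ratios κ_i = k_i/α; consequently only κ is inferable from a density profile,
and the additionally α-independent view κ_i/κ_L = k_i/k_L is provided for
cross-gene comparison.

## Exact solver (small lattices)

For small L the stationary master equation is solved exactly:
configurations (all A-site sets on 2…L with spacing ≥ ℓ) are enumerated
(count checked against a cap, default 2×10^5, before enumeration), the sparse
generator is assembled, and the stationary vector is obtained by replacing
one balance equation with the normalization Σ P = 1 and solving the sparse
linear system. The solver reports densities, per-bond currents (equal to
machine precision — the conservation oracle), the initiation current
α·P(first ℓ codons clear), and the per-codon conditional clearance
probability P(i+1…i+ℓ clear | A-site at i), which is the independent oracle
for the TEE identity. Exact solutions are feasible for test geometries
(ℓ = 1…3, L ≤ 8, hundreds of configurations), not for ℓ = 10 full-length
genes.

## Stochastic simulator

Gillespie sampling over the enabled-move catalogue (exponential waiting
times; numba kernel), so the sampled law is the process itself. Defaults,
chosen here since no canonical simulation budget exists: burn-in until
max(100, L) terminations complete; sampling window 2×10^4/α, which gives each
codon on the order of 10^4 occupancy transitions in the initiation-limited
regime; standard errors by batch means with 20 batches; an optional
`target_se` doubles the window (up to 3 times) until the worst relative SE is
met. Measured outputs: time-weighted densities, per-bond currents (event
counts/time), the clear-window time fraction (measured TIE) and the per-codon
conditional clearance time fraction (measured TEE). One seeded generator per
run; every seed is recorded.

### Statistical convention

Two stochastic quantities "agree" when they differ by less than 3 SE. Tests
that scan many codons at once treat this as the family-wise confidence level:
with batch-means SEs (Student-t, 19 df) and n simultaneous comparisons, the
per-codon cutoff is the Šidák-corrected t quantile at the single-comparison
3-SE level (≈4.2 for n = 6, ≈5.5 for n = 100). A naive per-codon 3.0 cutoff
over ~100 t-distributed comparisons would reject a correct simulator with
30–50% probability; the corrected threshold keeps the false-alarm rate at the
3-SE level while any systematic bias, which grows as √(sample time), still
fails it decisively. Density-agreement tests additionally require ≥99% of
codons within plain 3 SE.

## Initiation-limited approximation (ILA)

The fit's forward model is a systematic expansion of the stationary state in
powers of α, derived as follows. With the empty-lattice weight fixed to 1, a
configuration with n ribosomes has stationary weight O(αⁿ). Writing
one-ribosome weights as α·a_i + α²·b_i and two-ribosome weights as α²·c_ij,
the stationary balance equations close order by order:

* a_i = 1/k_i (in κ units, a_i = 1/κ_i);
* c_ij (i < j, j ≥ i+ℓ) satisfies a triangular recursion,
  c_ij = [α-inflow + k_{i−1} c_{i−1,j} + k_{j−1} c_{i,j−1}] / (k_i·1{j>i+ℓ} + k_j),
  where the α-inflow term a_j appears only for i = 2 and the c terms only
  when the source configurations are admissible — solved by an O(L²) dynamic
  program (numba);
* b_i follows a forward recursion driven by termination out of the {i, L}
  pair states and the initiation-blocking correction −a_i·1{i ≥ ℓ+2}.

Normalizing to second order gives ρ_i^ILA = a_i + b_i + C_i − a_i·Σ_m a_m
with C_i the total two-ribosome weight involving codon i. The truncation
error is O(α³): on exact-solvable lattices the max error falls by ~2³ when
uniform κ doubles (log-log slope ≈ 3), which the tests assert. Leading
behaviour is ρ_i ≈ 1/κ_i with a non-linear correction of relative size
≈(ℓ−1)/κ in the bulk; the expansion is reliable for min κ_i well above 1 and
degrades as initiation stops being rate-limiting — which is exactly what the
downstream quality check detects. A validity warning is emitted when
min κ_i < 1 (configurable threshold; a warning rather than an error because
the check handles breakdown explicitly).

## Mean-field approximation

The extended-particle mean-field closure in the MacDonald–Gibbs tradition,
written with windowed occupancy sums so it applies to inhomogeneous rates:

    J = k_i ρ_i (1 − Σ_{j=i+1}^{i+ℓ} ρ_j) / (1 − Σ_{j=i+1}^{i+ℓ−1} ρ_j),
    J = α (1 − Σ_{i=2}^{ℓ+1} ρ_i),

with sums truncated at L (sites beyond the lattice are empty) and the
termination relation J = k_L ρ_L. Forward solution: damped fixed-point
iteration (ω = 0.5 — the undamped sweep can 2-cycle when densities touch the
1/ℓ ceiling), convergence at 1e-10, cap 1e5 iterations, densities clipped to
[0, 1/ℓ] and denominators floored at 1e-12. Inversion (the optimizer's start
point and the per-codon fallback) evaluates the same relations at ρ = r
directly; the observed profile is then a fixed point of the forward map, so
the round trip reproduces r to solver tolerance. In the uniform dilute case
the inversion gives κ = (1 − (ℓ−1)r)/r — e.g. κ ≈ 91 for r = 0.01, ℓ = 10 —
i.e. the naive 1/r estimate carries a ~(ℓ−1)·r relative exclusion bias.

## Inference

The objective S = Σ_i (ρ_i^ILA(κ) − r_i)² is minimized by bounded
derivative-based least squares (scipy `least_squares`, trf) on log κ —
positivity by construction — with bounds κ ∈ [1e-3, 1e6] and finite-difference
Jacobians; the optimizer choice is ours (none is canonical). The start point
is the mean-field inversion. Zero-read codons imply an unphysically fast
codon: their κ is pinned to the upper bound, excluded from optimization, and
auto-flagged REJECTED_FIT_CHECK. Note the model has one κ per observed codon,
so at zero noise the fit recovers ILA-generated profiles exactly (S < 1e-12)
and small multiplicative noise is absorbed into κ at the same relative scale
rather than into S.

Quality check (one simulation per stage, per-codon errors read off the same
run): (a) |ρ^ILA − ρ^sim|/ρ^sim < 0.10 accepts the ILA estimate; failing
codons get their mean-field κ substituted, the mixed profile is re-simulated
once, and the mean-field prediction is re-checked at the same tolerance
(codons failing both: REJECTED_ILA_CHECK; if the mean-field iteration itself
does not converge on the mixed profile, the retried codons remain rejected);
(b) surviving codons require |ρ^sim − r_i|/r_i < 0.05 (else
REJECTED_FIT_CHECK). Both tolerances are relative and configurable, as are
the denominators (simulated density for (a), experimental for (b) — the
natural reference in each comparison). The reported κ carries the
least-squares values where the ILA was consistent and the mean-field values
elsewhere (the best remaining estimate). The termination codon κ_L is fitted
like any other codon; the κ_i/κ_L view is derived afterwards.

## Efficiency scores

TIE and TEE are defined through occupancy probabilities, so for a fitted gene
they are computed from the quality-check simulation (not from the analytic
approximations): TIE is the measured clear-window fraction; TEE_i uses the
identity TEE_i = TIE/(κ_i ρ_i) with the final κ and simulated ρ, masked to
accepted codons (mean TEE averages accepted codons only; the metagene
aggregator can include or exclude mean-field-accepted codons via a flag).
The identity is exact — it equals the conditional clearance probability at
machine precision in the exact solver — and is verified against the
simulator's direct measurement within statistical error. TEE values may
exceed 1 by simulation noise; they are clipped to [0, 1] with a logged count.
Collision times r_i/TIE − 1/κ_i are reported raw; negative values (possible
when profile and rates are inconsistent) trigger a warning, not an error.

## Synthetic data

Mock genes emulate the statistical structure the inference assumes: known
log-uniform κ (default [5, 50] on L = 150, ℓ = 10 — a regime with appreciable
traffic; uniform κ = 100 serves as the dilute control and κ_low < 1 as the
high-initiation stress case), stationary occupancy from the simulator, read
counts multinomial in the occupancy (reads conditionally independent given
occupancy) with total `depth`, and normalization that uses the simulation's
own mean density as the polysome-profiling value. An optional per-codon
log-normal multiplier injects overdispersion for robustness tests. Not
emulated: ligation/nuclease sequence biases, footprint-size distortions,
cycloheximide artifacts, disome loss, UTRs and multi-isoform ambiguity — so
passing tests demonstrate correctness of the inference given the model's
noise assumptions, not robustness to real library-preparation biases.

## Problem sizes

Exact-oracle comparisons use 20 random lattices with ℓ ∈ {1,2,3}, L ≤ 8 and
4×10^4/α sampling windows; parameter-recovery and quality-check studies use
single L = 150, ℓ = 10 genes at the 2×10^4/α default budget; the CLI tests run
a 4-gene cohort at L = 40. These sizes make the full suite run in about a
minute while keeping every statistical comparison well-powered.

## Known limitations

* Absolute rates are not identifiable from profiles alone — by design the
  package never reports k_i or α, only κ_i, κ_i/κ_L, TIE and TEE.
* The ILA is an expansion around rate-limiting initiation; in heavily
  congested genes most codons fall back to the mean-field estimate or are
  rejected, and the mean-field closure neglects correlations between closely
  spaced ribosomes (its error is uncontrolled, which is why accepted status
  still requires agreement with simulation).
* The exact solver is combinatorially limited to small lattices; at ℓ = 10 it
  serves no full-length gene, so all full-scale validation is statistical
  (simulation-based).
* The quality check's simulation makes the per-codon statuses stochastic at
  the margin: codons whose relative errors sit near a tolerance can flip
  between runs with different seeds.
* HDF5 count-table input is a best-effort reader for one documented layout
  (per-gene `reads` matrix keyed by a `lengths` attribute), not a general
  Riboviz-schema parser.
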