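# Methods

## Physical model

The system is a single detected ("free") ¹⁹F guest pool coupled to N minor
bound pools in star topology: each bound pool exchanges guest molecules
with the free pool only, since a guest leaves one host cavity before
entering another. Pool p carries magnetization (Mx, My, Mz) evolving under
Bloch relaxation (T1_p, T2_p), off-resonance precession at
Δ_p = δ_p − ω_rf, and RF nutation at ω₁ = γB₁ applied along x. Exchange
enters all three components with forward rate k_f,i = f_i·c_i·k_ex,i and
reverse rate k_ex,i, which satisfies detailed balance with the equilibrium
magnetizations M0_free = 1 and M0_bound,i = f_i·c_i by construction (the
package asserts this as a property: the generator annihilates the
equilibrium state when ω₁ = 0).

The inhomogeneous linear system dM/dt = AM + b is augmented with a
constant component, M̃ = (M, 1), so every constant-amplitude interval is
the exact map exp(Ã·t). `scipy.linalg.expm` evaluates the exponential; an
independent adaptive ODE integration (DOP853 at rtol 1e-11) serves as
cross-check in the tests, agreeing to ~3e-10 on random ≤3-pool instances.

Assumptions and simplifications:

- Saturation pulses are ideal rectangles (constant amplitude, no shape or
  duty cycle); there is no spatial/imaging dimension.
- Two-site Lorentzian exchange lineshapes only — no scalar coupling,
  chemical-shift anisotropy, or B0/B1 inhomogeneity.
- Bound-pool relaxation is weakly identifiable and defaults to
  t1_bound = t1_free, t2_bound = 0.02 s where not specified.

## Mixtures

Two rules turn a set of per-pair parameter records into a mixture sample:

- **Bound fractions scale linearly in host concentration**:
  f_i(c) = f_i,ref·c_i. At a 1:200 host:guest ratio the guest is in large
  excess, so doubling the host doubles the bound sites without depleting
  the free pool.
- **Free-pool relaxation rates are additive in agent concentration**:
  1/T1_free(mix) = 1/T1_dia + Σ_i c_i·(1/T1_free,i − 1/T1_dia), same for
  T2, with the diamagnetic (La) pair as baseline. This is the standard
  paramagnetic-relaxation-enhancement model; for a single pool at c = 1 it
  reduces exactly to that pair's observed values. Both rules are plain
  functions and can be overridden by constructing `Sample` directly.

## Acquisition protocol

40 saturation points in three blocks, each preceded by a 9.57 s recovery:
points 1–15 at 1.75 μT over the 14 library offsets plus a +200 ppm
off-resonance reference; points 16–30 the same offsets at 2.87 μT; points
31–40 a 10-point sweep of 1–11 ppm (where several bound-pool resonances
crowd) at 2.87 μT with shorter saturation. Saturation durations default to
4.0 s (blocks 1–2) and 2.0 s (block 3); only their ordering (block 3
shorter) is structurally required, and both are configurable. Within
blocks 1–2 the offsets are ordered reference-first, then descending |Δω|
(ties by value) — an arbitrary but fixed convention; what matters for
matching is only that it is deterministic and shared between dictionary
and query.

Fingerprint simulation carries the magnetization through every delay and
pulse sequentially (no full-reset assumption; 9.57 s ≈ 7–9×T1, so the
carry-over is small but not zero) and normalizes the trajectory by the
off-resonance reference point. During RF-free delays the longitudinal
subsystem decouples from the transverse one, so the recovery propagator is
evaluated once per sample in the free-guest frame and reused across
points; the only frame-dependent quantity is the phase of transverse
magnetization that has decayed by e^(−t_rec/T2) ≈ 1e-9 by readout time.
A z-spectrum point is the same pipeline started from equilibrium, with the
normalization reference simulated at the same power as the data point —
consequently a fingerprint equals the corresponding z-spectrum values only
for points sharing the reference's power (the single in-protocol reference
is acquired at 1.75 μT), which is how the equivalence is tested.

## Dictionary and matching

Hypotheses are unordered lanthanide subsets with one concentration factor
per member from a grid (full Cartesian product), enumerated in
lexicographic order: Σ_k C(n,k)·g^k entries. For the 14-member library at
sizes {1,2,3,5} this yields 2471 subsets; the default 5-level grid
{0.25, 0.5, 1.0, 1.5, 2.0} gives ~6.3M entries. Entries are float32 rows
in an HDF5 container, written chunk-by-chunk so the build is
memory-bounded and restartable at the chunk level.

Matching scores each entry by the inner product of L2-normalized vectors
(cosine similarity), accumulated over chunks; the top-k selection breaks
score ties lexicographically on the hypothesis key, making results
invariant to dictionary order and chunk size. The fidelity report is
R² = 1 − SS_res/SS_tot between the input trajectory and the best entry's
raw (un-normalized) simulated fingerprint.

## Z-spectrum fitting

`fit_zspectrum` jointly fits spectra at ≥2 saturation powers by bounded
trust-region least squares (`scipy.optimize.least_squares`, trf, numerical
Jacobian, x_scale='jac', ftol=xtol=gtol=1e-14). One power determines
essentially only the product f·k_ex; the B1 dependence of saturation
efficiency separates the factors. Fitted parameters: Δω, f, k_ex, T1_free,
and the ratio r = T2/T1 ∈ (0, 1]. The ratio parametrization enforces
T1 ≥ T2 as a box constraint; fitting T2 directly and clipping at T1 leaves
a zero-gradient plateau in which the optimizer can stall at a spurious
minimum. Bound-pool relaxation is held at the initializer's values.
Default bounds: Δω ∈ [−50, 50] ppm, f ∈ [1e-5, 0.05] (the 1:200
stoichiometry puts nominal f near 0.005), k_ex ∈ [10, 1e4] s⁻¹,
T1/T2 ∈ [0.05, 20] s. Non-convergence sets a flag rather than raising;
fits with f̂ ≤ 1e-4 are flagged unidentifiable, and a fitted offset
outside the acquired offset range clears `dip_in_range`.

Standard errors come from the Gauss–Newton curvature at the optimum,
cov = s²(JᵀJ)⁻¹ with s² the reduced chi-square; for noiseless synthetic
data they are effectively zero and serve only as relative diagnostics.

## Synthetic fixture library

The shipped 14-member library is synthetic: plausible per-pair values
reproducing the qualitative structure of a lanthanide series, not measured
constants. Anchored structure: Dy at −28.6 ppm; the diamagnetic pair La
(+0.8) and Lu (+1.4) only 0.6 ppm apart; total span 44.4 ppm (−28.6 to
+15.8); four members within 2 ppm of zero (La, Lu, Sm, Gd) to reproduce
the crowded near-resonance regime; Gd with a near-zero offset (no
pseudocontact shift from its isotropic f⁷ configuration) and strongly
enhanced relaxation (T1 0.25 s, T2 0.05 s). Exchange rates vary from 400
to 1800 s⁻¹ across the series; all bound fractions are f = 0.005 (1:200
host:guest). Free-pool T2 values (0.5–0.9 s; Gd excepted) are in the range
typical of small fluorinated molecules in solution, which keeps direct
saturation from overwhelming the exchange effects at the near-zero
offsets.

With these fixtures Gd's exchange-specific contrast — the maximum
deviation between its fingerprint and that of an otherwise identical
sample with f = 0 — is 0.03, versus ≥0.58 for every other member: the
"shallow fingerprint without clear peaks" regime. Its *relaxation*
signature remains strong, so unlike a real spectrometer measurement, Gd is
still reliably identified here; the synthetic benchmark therefore probes
the shallow-GEST regime but not the Gd misassignment failure itself.

The noise model is additive i.i.d. Gaussian noise on the normalized
signal, clipped to [0, 1.05] — a high-SNR magnitude-detection
approximation. It does not emulate B0 drift, phase errors, baseline roll
or correlated noise, so identification accuracies measured here are upper
bounds on what real spectra would give.

## Problem sizes and numerical choices

- Identification experiments run against the sizes-{1,2,3}, 3-level-grid
  dictionary (10,689 entries, ~35 s to build) with 100 seeded trials per
  mixture size at σ = 0.005 — large enough for stable accuracy estimates
  while keeping a full run in minutes on one core. The acceptance script
  uses 50 trials per size.
- Propagation is validated on 100 random ≤3-pool instances over intervals
  of 0.05–0.35 s; the oracle (DOP853, rtol 1e-11, atol 1e-13) is ~30×
  more accurate than the 1e-8 agreement bound.
- Fit-recovery experiments use two powers (1.75/2.87 μT), 60 offsets over
  [−34, 5] ppm, starting points perturbed ±20% from truth.
- Degenerate inputs: zero-power saturation leaves equilibrium fixed; f = 0
  pools contribute nothing (verified by symmetry of the resulting pure
  direct-saturation z-spectrum); the zero vector is rejected by
  `normalize`; constant experimental vectors are rejected by
  `fidelity_r2`; empty offset lists and mismatched lengths raise.

## Known limitations

- Dictionary storage is float32; scores computed in float64 after cast.
  Self-match scores are ≥ 1 − 1e-9 but not exactly 1.
- The concentration grid is shared by all subset members; per-size or
  per-member grids would need a trivial extension of `iter_hypotheses`.
- Only single-pair fitting is implemented (mixture z-spectra are simulated
  but not fitted); multi-start global optimization is left to the caller.
- Concentration estimation accuracy is limited by the grid; the matcher
  reports the grid point, not a continuous estimate.
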