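# Methods

## The decomposition model

Time-resolved difference data are modelled as

ΔS(q, tⱼ) = Σᵢ αᵢ(tⱼ)·Cᵢ(q) + X(q, tⱼ),

a sum of time-independent spectral components Cᵢ(q) with time-dependent
weights αᵢ(tⱼ) (chronograms) plus a residual X.  Nothing constrains the
weights: the model is plain linear algebra, and the residual is defined
so that `reconstructed + residual == signal` holds to floating-point
additivity.

The component set is assembled from two sources, physical priors first:

1. **Known components {Kᵢ}** — solvent heating curves measured with a dye
   control, artifact shapes obtained from pre-time-zero data, curves of
   known species.
2. **SVD-supplied components {Uⱼ}** — the significant left singular
   vectors of the whole data matrix, covering whatever the priors miss.

Because the combined set can be redundant (the data's singular vectors
already span everything, including the priors' directions), the set is
orthogonalized in order by modified Gram–Schmidt with one
re-orthogonalization pass, and each component's *remainder fraction* —
the norm left after projecting out all previously retained components,
divided by its own norm — is recorded.  A component below the dependence
tolerance is discarded: keeping it would make the weights non-unique.
Since priors come first, redundancy is always charged to SVD-supplied
components, never to the physics.

### Direct fit

The unweighted fit performs one QR factorization of the retained
components and solves the triangular system per delay; this is exactly
the least-squares solution (asserted against the pseudo-inverse in the
tests to < 1e-8; measured agreement is at rounding level, ~1e-15).  The
σ-weighted fit minimizes χ²(t) = Σ_q ((ΔS − Σαᵢ Cᵢ)/σ)² by rescaling the
rows of components and data by 1/σ(q, t) and redoing the QR at every
delay, since the row scaling is delay-dependent.  Pruning is decided once
on the unscaled set, so the model dimension is constant over time and
chronograms remain comparable across delays.

Numerical choices: dependence tolerance 0.05 by default (far above
double-precision rounding, well below the distinctness of genuine signal
components; configurable); flagged components keep their chronogram row
with weight zero so output shapes are stable; σ entries are required to be
strictly positive at load time; each left singular vector is sign-fixed so
its largest-magnitude element is positive (the paired right vector flips
with it), making every pipeline stage bitwise reproducible.

### Significance screening

How many singular components are "significant" is not decidable from
first principles, so two screens are combined: the singular value must
exceed 3× the median of the trailing half of the singular spectrum (a
robust noise floor), and the first-lag autocorrelations of both singular
vectors must exceed 0.6 (signal vectors are smooth; noise vectors are
not).  A `rank_override` bypasses the screen — in practice the count is
often fixed by inspection, and every demonstration here states the count
it uses.

## Posterior analyses

**Constrained spectrum retrieval.**  The singular component that carries a
physical signal is a mixture of that signal with artifact directions.
Under the constraint that artifact chronograms should only fluctuate
around zero, the physical spectrum is P(q) = C_target(q) + Σ_k βₖ·Cₖ(q)
with βₖ = ⟨αₖ, α_target⟩/⟨α_target, α_target⟩ — the closed-form minimizer
of the post-substitution artifact-chronogram energy
Σ_t (αₖ(t) − βₖ·α_target(t))².  The inner products run over all delays by
default (switchable to positive delays only).  The overall sign of P is a
convention (singular vectors carry arbitrary sign), so comparisons against
reference spectra use |cos|.

**Chronogram equivalence.**  When a candidate physical spectrum is an
exact linear combination of the retained components with unit coefficient
on the singular component, fitting with either gives identical chronograms
for the third component — a least-squares basis-change identity used both
as a correctness check and to justify analysing with U₁ in place of an
imperfectly known physical spectrum.

**Prior correction from the residual.**  If a prior spectrum is wrong, the
part of the data it cannot absorb accumulates in the residual with the
prior's own kinetics.  The residual's first singular component ρ(q) (after
the same significance screen; an insignificant residual returns the prior
unchanged) gives the correction direction, and the regression coefficient
of its temporal trace onto the prior's chronogram gives the amplitude:
corrected = C_prior + γ·ρ.  Only the out-of-span part of the distortion is
recoverable — the in-span part has already been absorbed by the other
components' chronograms.  This operation is an interpretation of a
procedure whose exact algebra is not published; its contract (cosine
improvement, γ monotone in the distortion, misfit never increased by the
correction) is what the tests pin down.

**Stationary zones and zone spectra.**  A window of `window` (default 5)
consecutive delays is stationary when every considered chronogram's
within-window range, normalized by its global dynamic range, stays below
`tol` (default 0.05); overlapping or touching windows merge into maximal
zones.  The normalization makes detection invariant to per-chronogram
affine rescaling.  Monotone backgrounds (solvent heating) must be excluded
via `exclude_labels` — they never go flat and would mask every zone, which
is precisely why separating them out first matters.  Zone spectra are
unweighted averages (σ-weighted behind a flag) of the data columns inside
a zone after subtracting the fitted contributions of the solvent labels.
Note that when the solvent chronogram comes from a fit whose basis
over-determines the temporal space (four physical chronograms spanning
three temporal directions), the subtraction is consistent but not equal to
the generator's truth; zone spectra then carry a fixed admixture that the
round-trip refit absorbs, which is why the round-trip is validated by
correlation (squared Pearson r) rather than by pointwise identity.

## Synthetic scenarios

The generators emit `signal = components @ chronograms + noise` with the
exact factors attached, so the ground truth defines correctness.  Component shapes are parametric families over the spectral
grid (damped sinusoids sin(f·q+φ)·e^(−d·q) and Gaussian-bump differences),
unit-normalized, chosen mutually non-orthogonal and similar in character
to difference-scattering curves.  Gaussian noise is calibrated so its RMS
is `noise_fraction` × RMS of the noiseless matrix; the emitted σ matrix
equals the true noise RMS (a signal-proportional σ model is available).

**Mock sequential reaction** (145 spectral points × 111 delays: 10 linear
negative delays −10…−2 ps plus 101 log-spaced 100 fs…100 ns; 6% noise).
Four components: intermediate (decay τ₁ = 100 ps), product (1 − e^(−t/τ₁)),
a systematic artifact present at all delays with a slow deterministic
drift in weight (a constant weight would make recovery R² undefined and is
also less realistic for a condition drift), and solvent heating rising
with τ_heat = 30 ps.  By default the four chronograms are independent
(rank 4); the `rank3` preset ties heating to product formation,
reproducing the situation where SVD finds only three significant
components for four-component data.

**Beam-instability scenario** (200 spectral points; 25 negative delays;
3% additive noise; artifact amplitude 1.0 per delay, heating amplitude
2.0, τ_heat = 100 ps).  Two fixed oscillatory artifact spectra carry
independent Gaussian per-delay amplitudes at *all* delays; heating rises
smoothly after time zero.  Three deliberate calibrations, made so the
scenario realizes the structure the workflow assumes: (i) the negative-delay block is dense and the additive noise
moderate because the artifact-subspace estimate from pre-time-zero columns
must be accurate to well under the 5% dependence tolerance for pruning to
be meaningful (the estimate's angular error scales as the noise-to-artifact
ratio over √n_negative); (ii) the heating amplitude is set so its coherent
chronogram gives it the largest singular value — the signal-carrying
component is then the *first* whole-data singular vector and the later
ones are the redundant ones, which is the configuration the greedy
in-order pruning assumes (with real data one reorders the selected
components by hand to the same effect); (iii) additive noise at 3%
reflects shot-averaged random noise, the dominant corruption being the
artifacts themselves.

**Two intermediates with heating** (145 × 111, all-positive log grid
3 ps…100 ns; τ₁ = 10 ps, τ₂ = 3 ns).  Standard sequential kinetics
A → B → product with instantaneous formation of A; heating rises with
both steps (0.6/0.4 split).  All four chronograms lie in the span of
{1, e^(−t/τ₁), e^(−t/τ₂)}, so the data rank is 3 and one heating prior
plus two SVD components give an exact-rank fit with no pruning.  The grid
starts inside the first decay (3 ps ≈ τ₁/3) so the earliest delays are
never flat enough to register as a plateau, and it contains no negative
delays, where all chronograms would be trivially flat.  Species spectra
use distinct oscillation periods (pairwise overlaps 0.05–0.11, never
exactly orthogonal).

### What the generators do and do not emulate

They emulate the structure that the method exploits: additive components
with separable q- and t-dependence, artifacts reproducible in shape,
pre-time-zero columns free of reaction signal, noise of known scale.
They do **not** emulate detector nonlinearity, q-dependent noise
correlations, timing jitter (smearing around t₀), solvent-response
dependence on temperature/density as separate terms, or shot-to-shot
intensity normalization errors.  Passing tests therefore demonstrate the
algebraic and statistical correctness of the workflow under its stated
assumptions, not robustness to every real-beamline pathology.

## Validation measurements

`sanod.benchmarks` (shared by `tests/test_acceptance.py` and
`scripts/acceptance.py`) regenerates all inputs from a seed and measures:
oracle deviations over 50 random problems up to 200×150 with up to 8
components; chronogram-recovery R² and misfit inflation under component
omission over 20 mock seeds; pruning and filtering success fractions over
20 beam-instability seeds; retrieval cosine and zone statistics as medians
over 5 seeds (both are single-number demonstrations of a stochastic
scenario; the median reports the typical outcome).  Problem sizes are the
scenario defaults throughout, and the whole battery runs in a few seconds.

## Known limitations

- Dependence pruning is greedy and order-dependent by design; a component
  set whose signal-carrying singular vector is not ordered before the
  redundant ones must be reordered by the caller.
- The weighted fit treats σ as independent per point; correlated errors
  are out of scope, and filtering does not propagate the (second-order)
  change in error correlations caused by subtracting fitted terms.
- Stationary-zone detection is a simple range test; it flags marginal
  windows near plateau edges and is not a substitute for full
  variable-time-range analyses.
- No interpolation anywhere: component sets must share the dataset's
  exact spectral grid, and a mismatch is an error rather than a silent
  resample (resampling would corrupt χ² weighting).
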