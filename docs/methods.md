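# Methods

## The two-rate model of MAC assembly

After C9 is added to a membrane carrying C5b-8 initiator complexes, pore
assembly is treated as two separate pseudo-first-order reactions in the
(excess, hence approximately constant) C9 concentration:

* **Initiation** — C5b-8 + C9 → C5b-8(C9)₁ with rate constant `k_init`.
  For a single complex the initiation probability is
  `p_init(t) = 1 − exp(−k_init[C9]t)`, so with N complexes on the membrane
  the expected number of visible pores follows the appearance curve
  `A(1 − exp(−t/τ_init))` with `τ_init = 1/(k_init[C9])` and saturation
  level A set by the number of initiators.
* **Propagation** — C5b-8(C9)ₙ + C9 → C5b-8(C9)ₙ₊₁ for 1 ≤ n < 18 with
  rate constant `k₊`. The occupancy distribution pₙ(t) of a single growing
  pore is a linear birth chain with intensity `λ = k₊[C9]` and absorbing
  state n = 18. Below the absorbing state the chain is a pure Poisson
  counting process, `p₁₊ₘ(t) = (λt)ᵐ e^{−λt}/m!`, and the mean oligomer
  size obeys `d⟨n⟩/dt = λ·(1 − p₁₈)`, i.e. growth is linear at rate λ
  while the absorbing state is still nearly empty.

The model's validity rests on the strong timescale separation
`τ_init ≫ τ₊` (two orders of magnitude for the MAC): each pore completes
quickly relative to the arrival of new pores, so pore *appearance* reports
initiation, and the within-pore height transition reports propagation.
One consequence, reproduced by the simulator, is that incomplete arc-shaped
pores are rare — monomer depletion never traps a growing ring.

### Units

Heights nm, times s, lateral distances nm (pixels where stated),
concentrations mM, rate constants s⁻¹ mM⁻¹. The kinetic time origin
(t = 0) is the moment of C9 addition.

## Estimation procedure

1. **Conditioning.** Each frame: least-squares plane subtraction →
   line-by-line flattening (median of background pixels per scan line) →
   Gaussian smoothing of 2 px FWHM. The bilayer background for the plane
   fit and flattening is selected automatically as pixels below
   median + 3·MAD of the frame; the original analyses pick the bilayer
   reference manually, and this robust rule is the automated stand-in
   (`n_mad` exposed).
2. **Detection.** Zero-mean, unit-energy (Pearson) cross-correlation of a
   complete-pore template over the valid overlap region; local maxima
   above 0.6 survive non-maximum suppression with exclusion radius of half
   the template width, ties broken in raster order. Pearson normalisation
   makes the 0.6 threshold contrast-invariant. The template is rendered
   noiselessly from the pore geometry and smoothed exactly like the
   movie frames.
3. **Tracking.** Greedy frame-order nearest-neighbour linking (max
   distance 30 px, gap closing up to 3 frames), deterministic by
   construction. Tracks with fewer than 3 detections are discarded — the
   automatable replacement for manual false-positive curation; nothing
   else is silently dropped.
4. **Height traces.** Per track, a square crop of 25 nm half-width around
   the median track position, starting 5 frames before first detection;
   the mean crop height per frame is the completeness proxy. For the
   oligomerisation statistics only *isolated* events are used (no other
   track centre within 50 nm, configurable), because a neighbouring pore
   inside the crop would superimpose a second transition on the trace.
5. **Transition fit.** Savitzky–Golay smoothing (window 7 frames, order 2)
   followed by nonlinear least squares of `A·tanh((t − t₀)/τ) + B` with
   bounds A, τ > 0; initial values A = (max−min)/2, B = mean, t₀ at the
   maximum discrete derivative, τ = span/4. QC rejects fits with t₀ < 0 or
   3τ longer than the movie. `τ_olig = 3τ` covers tanh(1.5) ≈ 90.5% of
   the amplitude. The summary reports mean, sd and sem over passing events.
6. **Rates.** `τ₊ = τ_olig/17`, `k_init = 1/(τ_init[C9])`,
   `k₊ = 1/(τ₊[C9])`. The appearance curve is fitted unweighted to the
   cumulative count of curated track births (raw per-frame detection
   counts are also available).

### Numerical choices

* The occupancy chain is propagated with the matrix exponential of the
  18-state generator, which conserves probability to machine precision and
  agrees with the Poisson closed form to < 1e-8 over λt ≤ 30.
* The tanh fit measures a *width* of a smooth fit to what is really a
  17-step staircase plus sampling: on simulated movies the mean fitted 3τ
  sits within ~10% of the true 17-addition completion time under the
  default crop window; that residual shape mismatch is inherent to the
  width definition and is well inside the 20% recovery tolerance used in
  validation.
* Savitzky–Golay smoothing leaves a polynomial trace exactly unchanged;
  on a noiseless tanh it biases τ by ~+1e-3 relative at τ ≈ 40–50 s
  (6.5 s sampling), shrinking rapidly for wider transitions.
* Degenerate inputs are flagged, not guessed at: flat traces skip
  normalisation, non-converged fits carry `fit_failed`, an all-zero movie
  aborts the pipeline at the detection stage with a named error.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes:

* first-insertion times exponential with rate `k_init[C9]`
  (default `k_init = 0.78 s⁻¹ mM⁻¹`, `[C9] = 1.4 µM`, so τ_init ≈ 916 s);
* 17 independent exponential inter-addition waits with rate `k₊[C9]`
  (default `k₊ = 108 s⁻¹ mM⁻¹`, so τ₊ ≈ 6.6 s and mean completion ≈ 112 s);
* each pore rendered as an annulus (11 nm lumen, 22 nm outer diameter,
  10 nm tall) whose arc fraction is n/18 with a fixed per-pore growth
  start angle (growth is unidirectional), on a flat membrane with
  additive Gaussian noise (default sd 0.3 nm), optional global tilt,
  drift and a taller C5b stalk;
* acquisition defaults 2 nm/px, 6.5 s/frame, 256×256 px, 500 frames
  (3250 s), 50 complexes placed uniformly with a minimum pairwise
  separation of one template width so ground-truth identity is
  unambiguous. Event times are rounded down to the frame in which the new
  state is displayed.
* a single integer seed drives independent substreams for positions,
  event times, growth angles and pixel noise, so changing the rendering
  never perturbs the sampled kinetics; identical seeds give bit-identical
  movies.

The membrane noise amplitude and drift of the original instrumentation
are not published; the defaults are engineering choices representative of
well-tuned fast-scanning AFM on supported bilayers, and are exposed in the
configuration.

What the generator does **not** emulate — and hence what passing recovery
tests do not demonstrate about real data: tip convolution and tip-shape
artefacts, scanner creep and nonlinear drift, scan-line noise correlated
with feature edges, partially-formed arc end states, transiently bound
pre-insertion intermediates, and pore-pore clustering. Real movies also
require the operator-facing choices (template selection, threshold tuning)
that the synthetic path fixes at defaults.

## Validation problem sizes

Recovery tests use 1,000 complexes × 10 seeds for the appearance curve
(≈3% statistical floor per seed, 5% tolerance), 33 traces per run for the
oligomerisation time (the size of the published event set), 10,000
stochastic chains against the occupancy solver, and one full 500-frame
default movie for end-to-end recovery of both rate constants within 20% —
a single movie carries only ~50 initiation events, so the initiation-rate
estimate has ≈14% statistical scatter and the tolerance is dominated by
counting statistics, not by systematic error.

## Known limitations

* Sub-pixel localisation, track merging/splitting and global-optimal
  linking are out of scope; the greedy tracker matches the described
  sequential procedure.
* The appearance fit has no time-offset parameter, so the detection lag
  of a growing pore (it must reach ~half a ring before correlating above
  threshold, ~9 subunits ≈ 60 s at the default geometry) introduces a
  small upward bias in τ̂_init, negligible when τ_init ≫ τ_olig.
* Whether published oligomerisation-time uncertainties are sd, sem or CI
  is ambiguous; summaries therefore report all of n, mean, sd and sem.
* [C9] depletion is deliberately not modelled (excess-C9 assumption is
  hard-coded); do not apply the rate conversions to movies where the
  monomer pool visibly depletes.
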