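# Methods

## Model and procedure

The package quantifies phase synchronisation in multivariate rhythmic
movement data.  Every statistic reduces to operations on unit phase
vectors exp(iθ): the cluster phase q(t) is the argument of the
participants' mean unit vector at each time step (the Kuramoto order
parameter's phase), and every synchrony degree — individual ρ_k, continuous
group ρ_group,i, trial-level ρ_group, dyadic ρ_d — is a mean resultant
length, i.e. the complement of a circular variance (ρ = 1 − V).

Assumptions worth making explicit:

* Signals are narrowband and quasi-periodic around a common tempo.  The
  Hilbert instantaneous phase is only meaningful for such signals; the
  statistics are not defined for broadband, non-oscillatory movement.
* All channels share one sampling rate and equal length; missing samples
  are rejected at ingestion rather than silently imputed.
* ρ_group subtracts each member's mean relative phase φ̄_k, so it measures
  the *stability* of the group's phase pattern, not its inphase-ness; the
  pattern itself is read from the φ̄_k table.
* The method is symmetric and instantaneous: it cannot attribute coupling
  direction, leader/follower roles, or coupling delays.

## Analysis chain and defaults

Conditioning runs downsample → centre → low-pass → optional trim:

| parameter | default | rationale |
|---|---|---|
| downsample factor | 2 | 120 Hz motion-capture recordings → 60 Hz; ~100 samples per 0.6 Hz cycle is ample |
| low-pass cutoff | 10 Hz | removes sensor noise far above movement frequencies (~0.6 Hz) |
| Butterworth order | 2, forward–backward | zero-phase filtering; a causal filter would inject frequency-dependent phase lag directly into θ_k |
| centring | on | the analytic-signal argument is biased by DC offsets |
| transient trim | off (0 s, 0 s) | trial statistics are conventionally computed on full trials; a (15 s, 0 s) trim is available for locked trials with a visible initial transient |

Down-sampling applies a zero-phase order-4 Butterworth guard at 0.8× the
new Nyquist frequency before decimation; at movement frequencies this is
inert, it only protects against aliasing of wide-band noise.

Phase extraction defaults to the Hilbert analytic signal.  Two numerical
choices matter:

* **Edge handling.** Each row is extended by three mean periods per end
  with a sinusoid least-squares-fitted to the outermost two periods (a
  harmonic continuation), and the extension is discarded after the
  transform.  Mirror reflection — the obvious alternative — leaves a slope
  kink at the splice whenever the trial is cut mid-slope, and the resulting
  phase ripple (~0.03 rad two periods in from the edge) is material for
  short test signals.  With the harmonic extension the edge error for pure
  tones is at rounding level.
* **Peak picking** (used by the frequency estimate and the alternative
  frequency-normalised phase): local maxima with a minimum separation of
  0.25/(expected max frequency) seconds (default max 2 Hz) *and* a
  prominence of at least 10% of the row's peak-to-peak amplitude; plateaus
  count once at their midpoint.  Separation alone is not sufficient — at
  20 dB SNR the in-band noise creates spurious local maxima on the flat
  tops of a 0.6 Hz oscillation and roughly quadruples the estimated
  frequency; the prominence floor removes them while leaving clean and
  plateaued signals untouched.  The peak-interpolated phase advances by
  exactly 2π between consecutive maxima, is linearly interpolated between
  them and linearly extrapolated (and flagged) outside the first/last peak.

Angles are stored in radians wrapped to (−π, π] (the branch cut resolves
+π → +π); report tables convert φ̄ and SDφ to degrees.  SDφ defaults to
the circular standard deviation √(−2 ln ρ), with the linear SD of the
centred relative phase available as an alternative — both are reported
because either convention appears in the movement-coordination literature.

### Degenerate cases

* A time step where the participants' unit vectors cancel (mean-vector
  modulus < 1e−9) has no defined cluster phase.  The step is flagged; by
  default it is excluded from the time averages (φ̄_k, ρ_k, ρ_group), with
  `include` and `error` policies available.  Silently keeping the arbitrary
  arctangent output would inject garbage angles into φ_k.
* A participant whose relative phase is uniformly spread has ρ_k ≈ 0 and an
  undefined φ̄_k.  ρ_group needs *some* offset for that member; the default
  substitutes 0 with a logged warning (any choice perturbs ρ_group,i by at
  most 1/n, and the situation arises by construction in the chance-level
  regime), with an `error` policy available.

## Synthetic-data generator

`simulate` integrates mean-field Kuramoto dynamics with phase noise,

dθ_k/dt = ω_k + K·r·sin(ψ − θ_k) + σ ξ_k(t),

by Euler–Maruyama at the output sampling rate (120 Hz, ≫ the 0.6 Hz
dynamics; step-halving agreement is checked in the tests), rendering
displacement as A_k cos θ_k plus white sensor noise.  Defaults emulate a
six-member rocking-chair-style session: natural frequencies Gaussian with
mean 0.6 Hz and SD 0.04 Hz (the between-member spread observed when a
common tempo is practised; self-paced groups spread more, 0.06–0.08 Hz),
phase noise 0.1 rad/√s, amplitude 1, sensor noise SD 0.02 (small relative
to unit amplitude), 180 s at 120 Hz.  `make_group_trial` presets the two
study regimes: `uncoupled` (K = 0, no information between members — chance
synchrony) and `coupled` (K = 2.5 rad/s, ~10× the frequency spread in
angular units and ~6× the critical coupling K_c ≈ 1.6 σ_ω, so the group
locks within seconds).

What the generator does *not* emulate: real chairs' non-sinusoidal
waveforms and amplitude dynamics, slow tempo wander, postural artefacts,
and any leader/follower asymmetry.  Phase statistics are insensitive to
waveform for narrowband signals (the tests assert Hilbert-vs-true-phase
agreement), so passing tests validate the statistics and pipeline — not
biomechanical realism.

## Surrogate chance levels

Three standard constructions, sharing the rule that each row's own
structure is preserved while between-row coupling is destroyed:
`time_shift` (independent circular rotations ≥ one mean period; exact
marginals; default, most conservative for oscillatory data),
`phase_randomize` (per-row Fourier-phase randomisation; exact amplitude
spectra), `row_shuffle` (re-pairing rows across recorded trials).  The
empirical p uses the add-one rule p = (1 + #{null ≥ obs})/(1 + n_surr), so
p = 0 is impossible.  Per-surrogate seeds are spawned deterministically
from one seed.  Note that for strictly periodic, frequency-matched signals
a time-shifted copy remains phase-locked (a constant offset), so the
time-shift null is conservative by construction; the separation between a
genuinely locked trial and its null remains large in practice.

## Behaviour at finite trial length

Two finite-size effects are worth knowing when interpreting values:

* **Self-inclusion.** Each member contributes weight 1/n to the cluster
  phase, so a member completely unrelated to the others still shows
  ρ_k ≈ 1/(2(n−1)) (≈ 0.10 for n = 6; closed form
  |E[(5e^{iδ}+1)/|5+e^{iδ}|]| = 0.1005), not 0.  ρ_k = 0 is an n → ∞
  idealisation.
* **Offset estimation.** φ̄_k is estimated from the same trial.  When
  relative phases drift slowly (few cycles per trial), this partially
  aligns members and inflates ρ_group above the analytic chance level
  √π/(2√n): six uncoupled oscillators at 0.04 Hz spread over 3 minutes
  read ≈ 0.40 rather than 0.362 (0.394 and 0.388 at 0.06 and 0.08 Hz
  spread).  The statistic itself is exact — on fast-mixing iid phases it
  returns 0.365 — and the surrogate null inherits the same inflation,
  which is precisely why chance levels should be estimated by surrogates
  rather than taken from the asymptotic formula.

Both effects are computed and asserted by the test suite and the
acceptance script, not quoted from elsewhere.

## Problem sizes

The test suite and acceptance script use trials the analysis is designed
for — 6 channels, 60–180 s at 60–120 Hz — with Monte-Carlo ensembles of
20–50 trials for the stochastic regime checks and 20–30 surrogates for the
null-distribution checks; brute-force oracle comparisons run at n ≤ 4,
N ≤ 16 where explicit scalar complex arithmetic is practical.

## Known limitations

* No coupling-direction, delay, or leader/follower inference.
* Phase extraction assumes a single dominant rhythm per channel; no
  protophase-to-phase transformation or wavelet phase is provided.
* The dyadic matrix is descriptive; variance decompositions across
  individuals/groups (multilevel or social-relations models) are out of
  scope and should be fitted with a dedicated mixed-model package.
* Surrogates are univariate per row; constrained multivariate surrogates
  that preserve cross-spectra would defeat the purpose of the null here.
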