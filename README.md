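# clusterphase

Cluster-phase analysis of group movement synchrony.

When several people move rhythmically together — rocking chairs in a circle,
an audience clapping, a rowing crew — how synchronised is the *group as a
whole*, and how tightly is each member locked to it?  Bivariate measures
(relative phase between two limbs) do not answer this for n > 2.
`clusterphase` implements the Kuramoto-order-parameter approach to this
problem for researchers in movement science, social psychology and
coordination dynamics: a group-level synchrony degree ρ_group, per-member
synchrony statistics (ρ_k, φ̄_k), pairwise dyadic synchrony ρ_d,
surrogate-data chance baselines, and a coupled stochastic-oscillator
simulator for validation.

## The statistics

For n movement time-series x_1(t_i), …, x_n(t_i) (one displacement channel
per participant), each channel is conditioned (down-sampled, centred,
zero-phase low-pass filtered) and converted to an instantaneous phase
θ_k(t_i) ∈ (−π, π] via the Hilbert transform (or a frequency-normalised
peak-interpolated phase).  Then:

1. **Cluster phase** — the group's central phase, the argument of the mean
   unit vector:

   q(t_i) = arg( (1/n) Σ_k exp(i θ_k(t_i)) )

2. **Relative phase** per member: φ_k(t_i) = θ_k(t_i) − q(t_i), wrapped.

3. **Individual synchrony** — circular mean and mean resultant length of
   each member's relative phase:

   φ̄_k = arg( (1/N) Σ_i exp(i φ_k(t_i)) ),  ρ_k = | (1/N) Σ_i exp(i φ_k(t_i)) |

   ρ_k = 1 means the member is phase-locked to the group up to a constant
   offset φ̄_k; ρ_k near 0 means unrelated.  (ρ = 1 − V, the complement of
   the circular variance V.)

4. **Continuous and trial-level group synchrony** — the order parameter of
   the offset-corrected relative phases, and its time average:

   ρ_group,i = | (1/n) Σ_k exp{i (φ_k(t_i) − φ̄_k)} |,  ρ_group = (1/N) Σ_i ρ_group,i

   Because each member's stable offset φ̄_k is subtracted, a group locked in
   *any* fixed phase pattern (not just inphase) scores ρ_group = 1.

5. **Dyadic synchrony** for each pair: ρ_d = | (1/N) Σ_i exp(i (θ_k − θ_k′)) |,
   with the mean dyadic relative phase φ̄_d.

For n independent (unsynchronised) members, ρ_group does not fall to 0: the
resultant of n independent unit vectors has expectation √π/(2√n) — ≈ 0.362
for n = 6.  The surrogate module estimates this chance level empirically
from the data themselves (time-shifted, phase-randomised, or trial-re-paired
copies), returning a null distribution, quantiles and an add-one-rule
p-value for the observed ρ_group.

## Worked example

The analyzers are scikit-learn style estimators, so the whole chain
composes as a pipeline:

```python
from clusterphase import (Preprocessor, PhaseExtractor, ClusterPhaseAnalyzer,
                          make_group_trial)

x = make_group_trial("coupled", seed=1)   # 6 channels, 180 s at 120 Hz
theta = PhaseExtractor().fit_transform(Preprocessor().fit_transform(x))
analyzer = ClusterPhaseAnalyzer().fit(theta)
print(round(analyzer.rho_group_, 4))      # 0.9972
print(analyzer.rho_k_.round(3))           # [0.998 0.996 0.998 0.994 0.999 0.998]
```

or in one call: `analyze_trial(x)` (equivalently
`ClusterPhaseAnalyzer(from_displacement=True).fit(x)`).

The same contrast from the command line:

```
$ clusterphase demo --seed 0
condition    rho_group  min rho_k  max rho_k
uncoupled        0.406      0.253      0.578
coupled          0.998      0.997      0.999
```

The coupled (visually informed) regime locks — trial-level group synchrony
0.998, every member's ρ_k near 1 — while the uncoupled (no-information)
regime sits near the six-member chance level (analytic 0.362; finite
3-minute trials with slowly drifting relative phases read slightly higher,
here 0.406, which is exactly what the surrogate null reproduces).

Other commands: `clusterphase simulate` (oscillator config → trial CSV),
`clusterphase analyze` (trial CSV → per-member table in degrees, group
summary, ρ_group,i series, dyadic matrix), `clusterphase surrogate`
(chance-level test).  Trial CSVs carry their sampling rate in a
`# sample_rate_hz=…` header line.

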