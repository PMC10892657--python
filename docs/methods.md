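# Methods

## Problem and scope

Two fingers executing a coordinated keystroke are treated as planar
three-link chains (proximal/middle/distal phalanges) hinged at the MCP,
PIP and DIP joints, with joint centers P₀–P₃ observed as 3D points. Only
the flexion/extension degree of freedom of the MCP joints enters the
model: the middle-finger MCP angle θ₁ (measured from the vertical +Z₀
axis to P₀→P₁), its derivatives ω₁ and a₁, and the ring-finger MCP angle
β₁ as the prediction target. PIP/DIP angles are extracted only as optional
outputs. Abduction/adduction, the thumb, and signal-based (non-metronome)
cycle detection are out of scope.

## Synthetic cohort generator

Real recordings of this protocol are private, so experiments run on
synthetic cohorts that reproduce the protocol's structure:

- **Cohort**: subject finger lengths are drawn from truncated normals
  (middle 84.4 ± 4.3 mm, ring 79.1 ± 4.5 mm, truncated to (40, 130) mm);
  training years uniform on [5, 15] (the study population is described
  only as having "several years" of training, so a flat band around a
  decade is used).
- **Keystroke waveform**: θ₁(t) = rest + A·sin²(πt/T) per cycle, with
  rest = 10°, A = 40°, T = 0.75 s — a C²-smooth single-peak flexion pulse;
  the waveform's functional form is not constrained by any measurement, so
  the simplest smooth pulse is used and all parameters are configurable.
- **Sampling**: 100 Hz (hand-tracking cameras of the class used for such
  recordings run 50–120 Hz), 25 cycles per set → 1875 frames per set.
- **Coupling law (ground truth)**: β₁(t) = offset + gain·θ₁(t − lag) with
  gain = 0.85 + 0.01·(ℓ_ring − ℓ_middle) + 0.005·years, offset 2°, lag
  0.05 s. Over the sampled population the gain stays in ≈(0.75, 0.95).
  Because θ₁ is sinusoidal, θ₁(t − lag) is an exact linear combination of
  θ₁(t) and ω₁(t), so the target is representable by the network class and
  parameter recovery is a meaningful test. A mild tanh-saturation variant
  (`CouplingLaw(saturating=True)`) is available for robustness
  experiments.
- **Geometry**: phalanx lengths are fixed fractions 0.46/0.31/0.23 of
  total finger length (a standard anthropometric split; only the proximal
  segment affects the MCP angle). PIP/DIP flexion is generated
  proportionally to MCP flexion (ratios 0.5/0.3). The ring-finger base
  sits one white-key width (23.5 mm) from the middle-finger base along
  −Y₀. Noiseless trajectories are exactly planar (x ≡ 0) and rigid.
- **Noise**: i.i.d. Gaussian angle noise (SD 2°) is added to every
  generating angle before forward kinematics, plus optional position
  noise (SD 0.5 mm) on all coordinates. The angle-domain term dominates
  and sets the irreducible prediction floor.

What the generator does **not** emulate: tracking dropouts and occlusion,
tempo drift and phase error relative to the metronome, within-subject
fatigue or learning across sets, correlated (non-white) sensor noise, and
any true biomechanical coupling beyond the injected law. Passing tests
therefore demonstrate that the pipeline recovers a coupling of the assumed
class under realistic noise — not that real pianists obey that law.

## Kinematics

θ₁ = arccos(Ẑ₀ · û) with û the unit vector along P₀→P₁; the dot product
is clamped to [−1, 1] so valid segments never yield NaN, and segments
shorter than 1e-6 mm raise an error naming the frames. Derivatives use
second-order central differences with second-order one-sided stencils at
the ends, on an enforced uniform grid; on the reference 0.75 s sinusoid at
100 Hz the analytic error bound is dt²·|f‴|/6 ≈ 0.39 °/s at interior
frames and twice that at the two boundary frames. An optional centered
moving average (odd window; 5 recommended for noisy data, 1 = off) is
applied to angles before differentiation and recorded in the split
descriptor. Cycles are segmented by the metronome period aligned to t = 0,
discarding any partial trailing window — the synthetic protocol is
phase-locked, so signal-based segmentation is unnecessary.

## Network and trainer

Single hidden layer, 13 tanh units, linear output. Features and targets
are min–max scaled to [−1, 1] with ranges captured on the training split
only; all reported errors are in denormalized degrees. The trainer is
full-batch Levenberg–Marquardt with an analytic residual Jacobian
(verified against central differences to 1e-5): solve
(JᵀJ + μI)δ = −Jᵀr via Cholesky (least-squares fallback when
ill-conditioned); accept the step and μ ← μ/10 if the MSE drops,
otherwise μ ← 10μ and retry, up to μ_max = 1e10. Stopping: `max_epochs`,
gradient ∞-norm below 1e-7, or μ exhausted. The accepted-step loss history
is non-increasing by construction. A stated "learning rate 0.01 / batch
32" configuration is implemented as an optional mini-batch
gradient-descent method for fidelity experiments; LM is the default
because it is the named training algorithm and has no learning rate.
Random initialization (plain BP) is uniform [−0.5, 0.5] from a seeded
generator.

## GA and SSA initialization

Both optimizers search the flattened weight vector (3·13+13+13+1 = 66 or
6·13+13+13+1 = 105 dimensions) within [−3, 3] per coordinate — enough to
saturate tanh units after normalization — with fitness = the candidate's
untrained forward-pass MSE. No gradient steps occur inside the fitness;
with population 50 and 100 iterations this is ~5×10³ forward passes, which
is the only budget-consistent reading of the configuration.

- **GA** (pop 50, 100 generations, p_c 0.6, p_m 0.2): tournament-2
  selection, whole-arithmetic crossover (one uniform mixing coefficient
  per pair), per-gene Gaussian mutation with SD = 0.1·range, 1-elitism
  (the incumbent's fitness is cached, so evaluations stay within the
  50 + 50·100 budget).
- **SSA** (pop 50, 100 iterations, explorer ratio 0.7, vigilante ratio
  0.2, safety threshold ST 0.8): per iteration the population is ranked;
  explorers shrink multiplicatively (X·exp(−i/(α·T_max)), α ~ U(0,1])
  while the per-iteration alarm value R₂ ~ U(0,1) is below ST, else take a
  shared Gaussian step; followers ranked in the worse half disperse toward
  the worst position, the rest step toward the best explorer along a
  random ±1 direction (the Aᵀ(AAᵀ)⁻¹ projection reduces to the mean signed
  distance added to every coordinate); a random 20% of vigilantes step
  toward the global best, or jitter in place when already best. All
  candidates are clipped to bounds.

Both optimizers are deterministic per seed, and both reach < 1e-2 on the
5-D sphere (bounds [−5, 5]) in 20/20 of the suite's fixed seeds.

A measured property worth stating plainly: on this synthetic target the
metaheuristic start is 5–10× better than the random one in initial MSE,
but LM then reaches the same noise-floor minimum from either start, so
*final training* MSE does not reliably separate the variants here; the
held-out RMSE comparison at full protocol scale does order SSA-BP ≤ BP in
the median. On data with genuinely multimodal loss surfaces the
initialization matters more; the easy representable target is a
limitation of the synthetic setting, not of the implementation.

## Evaluation

MAE, RMSE, and MAPE computed over frames (stated in each report's
metadata); MAPE uses a 1° denominator floor near the rest angle and
reports the number of excluded frames so the guard is auditable. Per-cycle
maximum absolute errors give the stability view. Splits: order-preserving
first-n/rest over sets (no shuffling — the held-out sets are later
recordings, as in the protocol), and leave-subject-out over cohorts. The
held-out partition is used purely as a test set; no model selection
touches it.

## Orchestration and problem sizes

Every stage seed derives from SHA-256 of (master seed, stage name), so
adding a variant never perturbs another's results, and outputs embed the
config hash and stage seeds. Training uses a deterministic uniform
decimation of training frames (default cap 30 000 of the 150 000–618 750
protocol frames) and metaheuristic fitness a further decimation (cap
8 000); with a 66–105-parameter model these caps leave estimates
statistically indistinguishable from full-data fits while keeping a full
protocol run in seconds-to-minutes on one core. The pipeline default of
100 LM epochs is far past convergence on this target (the gradient test
typically stops earlier). Evaluation always uses every test frame.

## Known limitations

- The trajectory CSV dialect is this package's own; it is *not* a
  hand-tracker log format.
- The coupling law is an invention required to make the problem testable;
  its parameters were chosen once for plausibility (ring excursion
  slightly smaller than middle, small positive training effect, 50 ms
  lag) and are not fitted to any human data.
- Predicted ring-finger angular velocity, if needed, is obtained by
  differentiating the predicted β₁ series; the model's output is β₁ only.
- Metrics are frame-based; cycle-averaged variants would weight short
  test sets differently.
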