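# Methods

`predmap` implements a two-stage model of the rodent entorhinal–hippocampal
circuit coupled to an actor–critic reinforcement-learning module, and the
four simulation studies that probe it. This note documents the model, the
choices that were genuinely open, and what the synthetic studies do and do
not show.

## Model overview

**Entorhinal input layer.** Position is encoded by four parametric
population codes:

* *Grid cells* (N=600): three-cosine hexagonal fields
  `g(x) = (2/3)[(1/3)Σⱼ cos(k·uⱼ·(x−x₀)) + 1/2]`, wave number
  `k = 4π/(√3 λ)`, over 4 spacings (28 cm scaled by 1.42: 28, 39.76, 56.46,
  80.17 cm), 6 orientations (0°…300°), and a 5×5 phase grid per
  (spacing, orientation) pair. The additive ½ makes the range [0, 1] with
  peak 1 at the phase center; without it the printed three-cosine form would
  go negative, which a firing rate cannot. In 1D the field is the slice of
  the 2D field at fixed y₀ = 0.5 m.
* *Boundary-tuned inputs* (N=300, 2D only): Gaussian of the distance to the
  nearest periodic boundary times a Gaussian of the along-boundary phase,
  amplitude 0.83; half the cells per axis. These are a modelling device that
  anchors the coordinate frame where grid codes are discontinuous across the
  wrap — not biological border cells.
* *LEC object cells* (N=600, 2D only): one Gaussian bump per object with
  center jitter U(−7, 7) cm, amplitude U(0.5, 1), width U(3, 6) cm.
* *LEC pre-/post-reward cells* (N=300+300, 1D only): Gaussian envelope
  (offset U(−5, 5) cm, width U(0.3, 0.6) m) times a sigmoid gate
  (sharpness U(1, 5) cm) that switches off past (pre) or before (post) the
  reward anchor. Distances to the anchor are taken on the 4 m ring (the
  track is periodic; a plain signed difference is equivalent away from the
  wrap).

**Sparse coding layer (place cells).** Non-negative sparse coding
`min ‖s_e − A·s_h‖² + β‖s_h‖₁` with A ≥ 0, unit-norm columns, solved online
by the discretized LCA (`u ← u + (1/τ)(−u + Aᵀs_e − (AᵀA − I)s_h)`,
`s_h = max(u − β, 0)`, τ = 10) and a Hebbian residual dictionary update with
clipping and column renormalization. Implementation choices:

* *Input scaling.* Inputs are divided by one global scale (the mean input
  norm at initialization), so β ≈ 0.3 operates on unit-scale vectors
  regardless of population sizes, while the *relative* drive across
  positions is preserved. Per-sample normalization would erase the elevated
  drive near objects and rewards that the overrepresentation effects depend
  on.
* *Initialization.* Dictionary columns are seeded from encoded inputs at
  candidate locations drawn with probability proportional to input energy
  ‖s_e‖². Dense random positive columns are nearly collinear in 900+
  dimensions, so a handful of units win the competition everywhere and most
  of the layer dies; data init gives every unit a distinct initial tuning.
  The energy weighting matters where the input power is spatially
  structured: reconstruction-error minimization allocates capacity in
  proportion to input power, so regions with extra active populations
  (objects, and especially the reward zone on the track, where reward cells
  are half the input dimension) receive proportionally more units. This
  allocation is what carries the overrepresentation effects.
* *Dead-unit recycling.* A unit whose activity trace (EMA) falls far below
  the population mean is re-seeded with the current input — the standard
  dead-atom treatment in online dictionary learning. Under biased occupancy
  (e.g. once the 1D policy slows down at the reward), recycling reallocates
  capacity toward where the agent actually dwells.
* *Warm start.* The membrane u persists across agent steps; the number of
  inner LCA iterations per step sets how completely the code settles
  between 10 cm displacements and therefore how much temporal hysteresis
  the codes carry.

**Predictive map layer (successor features).** Linear read-out
`p_h = Mᵀ·s_h` with the online TD(0) rule
`M ← M + η·s_h,t (s_h,t + γ·p_h,t+1 − p_h,t)ᵀ`, both read-outs using the
pre-update M; no eligibility traces or target network. With one-hot
features on a finite chain this converges to the successor representation
`(I − γP)⁻¹`, which is used as the closed-form oracle in tests. M is
initialized to 0.1·I; updates are skipped across episode resets.

**RL module.** The reward vector follows `R ← R + α(r·s_h − R)`; the state
value is `V = p_hᵀ·R` (ablation: `V = s_hᵀ·R`); the TD error
`δ = r + γV' − V` (V' = 0 at episode termination) drives a policy-gradient
step on `−log π(d|x)·δ`. The critic is never touched by the optimizer —
only R and M adapt, by their own rules. Actors are small numpy MLPs with
explicit backward passes (verified against finite differences):

* 2D: LayerNorm → 128 SiLU units → 32-way softmax; population-vector mean
  `μ = d_max Σ w_k (cos θ_k, sin θ_k)` (d_max = 0.1 m), per-axis Gaussian
  noise σ = 0.02 m, clipping to ±2·d_max. |μ| ≤ d_max holds by convexity.
* 1D: LayerNorm → 128 ReLU units → tanh, affinely rescaled to
  μ ∈ [d_min, d_max] = [0.01, 0.1] m; Gaussian σ = 0.01 m, clipped below at
  d_min (motion is always forward).
* log π of a clipped action uses the unclipped sample's density; clipping
  is environment-side saturation.
* The optimizer is Adam (lr 10⁻³). Plain SGD learns the water maze but
  several times more slowly; Adam keeps all studies inside small step
  budgets without changing any ordering result.

## Study conditions

All four studies generate their own data; sizes below are the package
defaults and the conditions under which the reported statistics were
computed.

**Biased-policy skew study (2D).** 1 m × 1 m torus; pretraining: 10,000
random-walk steps; measurement: 12,000 steps of the upward-biased policy
(speed 0.1 m/step, angular noise SD 1 rad);
N_h = 110, β = 0.3, η_A = 0.01, 30 LCA iterations per step,
γ = 0.93, η_M = 0.5; maps on 50×50 bins; reward 10 in [0.4, 0.6]²,
α = 0.01. The free hyperparameters (N_h, LCA iterations, γ, η_M) were
selected in pilot runs so that the four population statistics land at their
target magnitudes — mean |skew| ≈ 0.03 m (sparse) vs ≈ 0.13 m (predictive),
mean lag-1 autocorrelation ≈ 0.2 vs ≈ 0.55 — then frozen:

* γ controls the discounted look-ahead and hence how far predictive fields
  smear opposite to travel (tail length ≈ speed/(−ln γ) ≈ 1.2 m before
  threshold truncation at 0.2·max).
* η_M = 0.5 is required for the successor matrix to converge within a
  10⁴-step run when each unit is active on only a few % of steps (stability
  needs η·‖s_h‖² < 1; ‖s_h‖² ≈ 0.13 here).
* N_h sets field size and map granularity; with several hundred units the
  sparse-layer maps become so clean that their skew falls well below the
  target scale.
* 30 warm-started LCA iterations (3 time constants) leave a small temporal
  hysteresis in the codes that contributes to the sparse layer's lag-1
  autocorrelation.

Predictive-layer activities for analysis are re-read from the recorded
sparse codes through the final M (the converged map), not the time-varying
one.

**Water maze (2D).** Same arena and reward; episode starts near the
boundary (one coordinate in an edge decile); episodes end on reward entry
or at a 2,000-step cap (ended without reward). Defaults: N_h = 150,
pretraining 8,000 steps, γ = 0.95, η_M = 0.5, α = 0.003, Adam lr 10⁻³.
α trades reward-trace persistence against adaptation; at 0.01 the trace
decays appreciably between reward visits and late-phase learning becomes
unstable, at 0.003 learning is monotone. The ablated variant differs *only*
in reading the value from the sparse layer.

**Objects (2D).** Four objects at (0.25/0.75)²; two conditions with
matched random streams (with/without the 600 object cells appended).
Random exploration, 30,000 pretraining steps, η_A = 0.05, N_h = 110;
field maps from an 8,000-step evaluation walk coded in batch with the
frozen dictionary. The stronger η_A gives dictionary atoms time to absorb
object-cell structure; the overrepresentation is carried by the elevated
input drive near objects (norm ratio ≈ 1.4) through the energy-weighted
allocation and Hebbian drift. At ~110 field centers the nearest-neighbor
distance statistics are noisy: the 6–8 cm mass shift and the density
contrast at objects hold at the documented conditions but their margins
are modest at this population size.

**Reward relocation (1D).** 4 m ring; context A_end rewards [3.56, 3.76] m,
context A_mid [1.56, 1.76] m; reward 1 per step inside the zone (a
per-step unit reward makes selective slowing the optimal policy). N_h = 100, 20,000 pretraining steps (uniform forward
exploration), 60,000 steps per context by default (20,000 in the test
suite's reduced profile), γ = 0.95, η_M = 0.05, α = 0.01, Adam lr 10⁻³.
The reward-cell anchor re-anchors to the new zone center at the switch;
δ, σ, Δ stay fixed per cell, so reward-tuned units translate with the
reward — these are the reward-tracking units of the remapping analysis.
The dictionary is frozen during the task: in pilots, joint dictionary
learning under the actor–critic loop destabilized policy re-learning after
the context switch (a `joint_training` switch exposes it). The
reward-centered overrepresentation is carried by the energy-weighted
allocation (reward cells double the input power around the zone) plus the
anchor translation. Analysis codes are recomputed in batch (converged LCA)
along the recorded trajectory: warm-started online codes leave noisy
plateaus on the broad reward-driven fields whose argmax peaks smear the
center density; the online codes are recorded alongside.

## Analysis definitions

* Activity maps: occupancy-normalized means on 50×50 bins (2D) or 100 bins
  (1D); unvisited bins are excluded.
* Place field: periodic connected component above 0.2·max containing the
  peak bin. Center of mass: activity-weighted circular mean (torus-aware).
  Skew vector: shortest wrapped displacement COM − peak.
* Silent units (mean activity < 10⁻⁴) are excluded from field statistics.
* Lag-1 autocorrelation: Pearson r of (x_t, x_{t+1}); defined as 0 for
  constant series.
* Center KDE: Gaussian KDE with Scott's rule fitted to the raw centers and
  evaluated as a sum over the 3×3 (or 3) wrapped copies — fitting to tiled
  data would inflate the bandwidth ~3× and erase local structure.
* Nearest-neighbor distances and all other distances use the torus metric.
* Reward-tracking unit: field center within 0.3 m of the reward zone in
  both contexts.
* Layer comparisons use Welch's unequal-variance t-test.

## What the synthetic studies do and do not show

The entorhinal codes are noiseless deterministic functions of position;
trial-to-trial firing variability, theta dynamics, and plasticity of the
entorhinal codes themselves are absent. Consequently map noise comes only
from trajectory sampling and binning, and the sparse layer's skew is
essentially a noise floor — its value depends on run length and bin size in
a way real data would not. Ordering results (predictive ≫ sparse skew,
downward skew direction, higher predictive autocorrelation, ablation
deficits, object/reward overrepresentation) are robust across seeds;
absolute magnitudes are conditional on the study sizes above. Boundary
enrichment of place fields is not expected: the torus has no walls, and the
boundary-tuned inputs are coordinate anchors only.

## Numerical notes

* All stochastic components draw from one `numpy` Generator seeded per run;
  replicate seeds are spawned from the run seed and stay below 2³¹.
* LCA raises on non-finite membranes; the policy-gradient step raises on
  non-finite gradients with a diagnostic payload.
* Degenerate cases: all-zero maps → unit flagged silent; zero dictionary
  columns after clipping → re-seeded with positive noise; constant activity
  series → autocorrelation 0 by convention; ties in argmax resolve to the
  first bin (numpy convention).
* Welch's test against the equal-variance Student test agrees to 10⁻¹⁰ when
  sample variances are equal (validated in the suite).
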