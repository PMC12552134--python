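# Methods

This note records the model, the procedures, the defaults, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model and integration

Networks are continuous-time rate RNNs,

    τ ẏ = −y + f(W_rec y + W_inp u),      ô = W_out y,

discretized by a first-order Euler scheme with time step dt = 1 ms and
γ = dt/τ:

    y_{t+1} = (1−γ) y_t + γ f(W_rec y_t + W_inp(u_t + √(2γσ_inp²) ζ_t)
                                + √(2γσ_rec²) ξ_t),

with ζ, ξ i.i.d. standard normal. Activations: ReLU max(0, x), logistic
sigmoid 1/(1+e^(−7.5x)) with fixed slope 7.5, and tanh. The readout is
applied to the state *after* each update, so outputs and targets share the
same step index.

Defaults (configurable): τ = 10 ms (γ = 0.1), σ_inp = σ_rec = 0.01,
N = 100 units at full scale. Noise is on during training and off in all
analysis simulations, which makes every geometric summary deterministic
given the trained weights. The initial state is y₀ = 0.

## Initialization

Without Dale's constraint, W_rec entries are N(1/√N, 1/N²); with it,
excitatory columns are |N(1/√N, 1/N²)| and inhibitory columns
−|N(R_EI/√N, 1/N²)|, where R_EI is the excitatory-to-inhibitory count
ratio (4 for ReLU/sigmoid, 1 for tanh; N must be divisible by R_EI + 1).
W_rec is then rescaled so its spectral radius is exactly 1.2 — a positive
scalar, so the Dale sign pattern survives. W_inp and W_out start as
|N(1/√N, 1/N²)| and remain elementwise non-negative throughout training in
every architecture.

## Training

The loss is the masked mean-squared output error plus an activity penalty
λ_r·mean(y²) and an input-column orthogonality penalty
λ_⊥·mean‖offdiag(W_inpᵀW_inp)‖² (λ_⊥ = 0.1 by default). Optimization is
Adam (lr 0.001 full scale, β₁ = 0.9, β₂ = 0.999, ε = 1e−8) on analytic
gradients obtained by backpropagation through time through the Euler
recursion; the gradient code is verified against central finite
differences to ~1e−9 relative error in the unit tests. Gradients are
global-norm clipped to 1.0 (per network) before the Adam update. Clipping
matters most for relu networks without Dale's constraint: the stated
initialization gives W_rec all-positive-mean entries at spectral radius
1.2, so with an unbounded activation the initial forward pass explodes
(loss ~1e5–1e6) and the resulting giant first gradients would otherwise
poison Adam's second-moment estimates and stall training for thousands of
iterations. After every update,
negative W_inp/W_out entries and sign-violating W_rec entries are zeroed
(projected gradient descent), so the constraints hold at every step, not
just at convergence.

Schedules: CDDM and Go/NoGo train with λ_r = 0.5 for 5 000 iterations at
full scale; the memory task trains λ_r = 0 for 6 000 then λ_r = 0.3 for
6 000. Every iteration presents the complete condition set (the CDDM batch
is all 450 conditions) with fresh process noise.

`train_population` trains many same-shape networks jointly by stacking
weights along a leading batch axis; each network's loss and gradient are
identical to the single-network path (asserted to machine precision in the
tests). When numba is importable the inner loop runs as a compiled kernel;
the pure-numpy implementation is retained and is the reference the kernel
is tested against.

## Tasks (the synthetic-data stage)

Time is a 0-based 1-ms step grid; printed intervals are half-open.

* **CDDM**: 300 steps, 6 inputs (2 one-hot context + 2 channels per
  modality via c ↦ ((1+c)/2, (1−c)/2)), 2 outputs (right, left; 'right'
  is positive coherence). Context is on from t = 0; sensory channels from
  t = 100. Targets: 0 before 100 ms; from 200 ms the output matching the
  sign of the relevant coherence is 1 (both 0 at zero coherence). Mask:
  [0,100) ∪ [200,300); the integration window is unpenalized. The training
  grid is the 15-coherence set {0, ±0.01, ±0.03, ±0.06, ±0.13, ±0.25,
  ±0.5, ±1}, i.e. 450 conditions.
* **Go/NoGo**: 60 steps, value channel sustained, Go cue sustained at 1
  from t = 30 (a 1-step pulse would be fragile at dt = 1 ms), bias channel
  1 throughout. Target Θ(value − 0.5) after the cue (0.5 at threshold).
* **Memory number**: 100 steps (response window [70,100)); the value is on
  for 10 ms from an onset drawn uniformly from [0, 20] ms; target is the
  value after the cue at t = 70.
* Go/NoGo and memory masks cover all steps except a 5-step grace window
  after cue onset, paralleling the CDDM grace period.
* **3-bit flip-flop**: ±1 pulses per channel; each output holds the sign
  of the last pulse on its channel.

Batches are bit-identical given the same seed.

## Fixed points

For each constant input u, roots of F(y) = −y + f(W_rec y + W_inp u) are
found with scipy's hybrid-Powell solver given the analytic Jacobian
−I + diag(f′)W_rec. Starts are trajectory states from the second half of a
random trial plus N(0, 0.01)-variance jitter (std 0.1). Acceptance
‖F‖² ≤ 1e−12; duplicates closer than 1e−7 are discarded; the per-input
loop stops at 100 distinct points or 100 consecutive non-discoveries
(both scaled down in tests). Stability: principal eigenvalue (largest real
part, ties broken by larger |Im|) of the Jacobian, stable iff Re ≤ 0 —
marginal cases count as stable. The CDDM survey uses 2 contexts × 5
relevant × 5 irrelevant coherences {−1, −0.25, 0, 0.25, 1} (50 inputs);
the value tasks use each training value with the cue off and on.

## Geometry

All four summaries are PCA projections of the noiseless response tensor
Z (N × T × K), normalized by dividing by the square root of total variance
so every summary has unit total variance (the scale-normalization makes
networks of different activity magnitudes comparable):

* trajectories — 10 PCs over the unit axis of the (N, T·K) matrix;
* selectivity — 10 PCs over the time×trial axis (one point per unit);
* fixed points — 7 PCs of the stacked survey points, tags preserved;
* endpoints — last state of each trial, 10 PCs (one point per trial).

Trajectory/endpoint distance: regress summary i onto j and j onto i by
intercept-free least squares over the component axis; the distance is the
mean of the two residual mean-squared errors (exactly symmetric, zero under
invertible linear maps; data are PCA-centered so no intercept is needed).

Selectivity/fixed-point distance: ICP registration — random orthogonal
initialization, closest-point matching (one-to-many allowed; restricted to
equal (input, stability) tags in fixed-point mode; tags present in only one
cloud are excluded with a warning), orthogonal-Procrustes update, iterate
to convergence (relative improvement < 1e−6 or 100 iterations). Each
direction keeps the best of n_tries = 60 starts; the distance is the mean
of the two directional scores. Besides Haar-random starts, one
deterministic moment-matched start (principal-axis alignment with
skewness-disambiguated signs) is included; it can only lower the reported
minimum and makes registration of exactly-rotated clouds reliable when
n_tries is reduced in tests.

MDS: metric SMACOF on the precomputed distances, 8 random restarts plus
one classical-scaling start (exact when the distances are realizable in
2-D), best stress kept; stress-1 is reported.

## Latent circuits

Responses are reduced to z = 30 PCs over units, then an 8-node circuit
with the same activation and integration constants is fitted by Adam
(lr 0.01) on analytic gradients of

    L = ⟨‖o − w_out x‖²⟩ + λ_emb⟨‖Qx − z‖²⟩
        + λ_w(⟨w_inp²⟩ + ⟨w_rec²⟩ + ⟨w_out²⟩),

λ_emb = 20, λ_w = 0.001, means over all tensor entries, o the task target
(unmasked, matching the loss definition; the behavioural R² in `score_fit`
is computed on masked steps). The embedding weight is the one genuinely
sensitive hyperparameter here: networks trained under the activity penalty
have small-amplitude responses (z entries with std ~0.05–0.15), so with
λ_emb near 1 the embedding term is orders of magnitude below the O(1)
output term and the fit collapses to output-matching with arbitrary
dynamics (negative dynamics R²). λ_emb = 20 balances the two terms across
the architectures examined; it is configurable per fit. The weight decay
is kept small (λ_w = 0.001) for the mirror-image reason: small-amplitude
latent states need large readout weights to produce O(1) outputs, and a
decay term that rivals the output error caps the attainable behavioural
fit. Constraints after every step: clip negative
w_inp/w_out, re-zero masked w_inp entries (each input channel wires to at
most one node — channels 0–5 to nodes 0–5, nodes 6–7 input-free choice
nodes), and re-orthonormalize Q by QR with positive diagonal. Each restart is scored by the two
R² metrics and the restart with the best summed R² is returned (selection
by raw loss is available but, with the embedding term dominating the loss,
can return circuits that reproduce the dynamics while missing the
behaviour); ≥ 30 restarts at full scale, 10 or fewer in tests. R² uses
the grand-mean baseline over all compared entries.

The self-recovery test embeds a hand-designed 8-node context-gating
teacher through a random orthonormal Q with 1% additive noise and checks
the fit recovers its dynamics and connectivity. The teacher uses moderate
weights so every node spends time in the responsive region of its
activation; a teacher whose inhibited nodes sit deep in the ReLU dead zone
leaves those weights unidentifiable from dynamics — an identifiability
limit of the problem, not of the optimizer.

## Behavior

Task performance is the masked m.s.e. of a noiseless pass (used to rank
networks; lower is better). Psychometric maps simulate each (motion,
colour) coherence cell n_reps times with noise; the choice is the sign of
the time-averaged (right − left) output over the final 100 ms, and the
cell statistic the fraction of rightward choices. Out-of-distribution
probes extend the irrelevant-coherence axis to ±2 (relevant within ±1);
`irrelevant_sensitivity` is the irrelevant-coherence coefficient of a
least-squares linear fit of choice fraction on (1, relevant, irrelevant).
For the architecture-dissociation test the irrelevant grid is restricted
to the amplified range |c| ∈ [1.25, 2]: inside the training range all
architectures are insensitive by construction, so including it only
dilutes the out-of-distribution signal the probe is after.
Output-subspace alignment is ρ = ‖W_out X‖_F/(‖W_out‖_F‖X‖_F) over the
output epoch ([200,300) ms for CDDM, post-cue otherwise).

The flip-flop construction is three tanh units with self-weight 2 (two
stable states at ± the root of y = tanh(2y) ≈ ±0.9575), identity input
wiring with gain 2, and readout scaled to ±1; verification simulates all
8 bit patterns and requires each output to hold the written sign within
0.5 for 200 steps. The identical construction with ReLU units cannot hold
negative bits.

## Scale profiles and what the tests show

The full profile matches the study (N = 100, 100 networks per
architecture, printed iteration counts). The test suite runs a scaled-down
profile chosen for a single CPU: the architecture-comparison populations
are 18 networks of 20 units trained 500 iterations (three per
architecture, three master seeds); the deeply trained populations used for
distillation and the out-of-distribution probes are 50-unit networks
trained 2 500 iterations in single precision on the 5-coherence CDDM grid
(50 conditions); latent-circuit fits use 5 restarts of 2 500 Adam steps. At this scale the
qualitative phenomena — low-dimensional dynamics, architecture clustering,
the inhibition-vs-saturation gating dissociation under amplified
irrelevant stimuli — are all reproduced by the tests, but quantitative
values (fit R², silhouette magnitudes) sit below the full-scale ones, and
single networks occasionally fail to train well (medians over networks are
used where that matters). The generators emulate the stated input-channel
structure, grids, masks and randomized onsets exactly; they do not model
trial-to-trial adaptation, reaction times, or continuous coherence
sampling, so passing tests speak to the idealized task ensembles, not to
behavioural data.

`scripts/acceptance.py` trains one 50-unit tanh+Dale network on the full
450-condition grid for 400 iterations and reports the variance captured by
30 and 10 unit-axis PCs of the noiseless response matrix, in percent.

## Numerical notes and limitations

* Spectral-radius rescaling uses dense eigenvalues; exact to ~1e−12.
* The ReLU derivative at exactly 0 is taken as 0.
* Process noise is drawn in float32 for speed and promoted on use; the
  compiled training and fitting kernels optionally run entirely in float32
  (`precision="single"`), which changes individual stochastic-gradient
  trajectories but not the statistics of trained networks.
* Degenerate inputs raise: empty masks, zero-variance summaries,
  all-identical endpoints, zero-norm readouts, all-same-choice
  psychometric maps.
* ICP with few restarts can overestimate distances between very dissimilar
  clouds (local minima); distances within and between architecture
  clusters are affected equally, so embeddings remain interpretable.
* The joint-training population shares no gradients between networks, but
  BLAS summation order makes population and single-network training agree
  only to ~1e−9 per iteration in float64; tests compare with tolerance.
* No GPU paths, no alternative optimizers, no softplus or other
  activations, no bifurcation tracking, no topology-graph analysis.
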