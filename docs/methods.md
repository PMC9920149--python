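# Methods

## Model

Gaze position `x(t) ∈ R²` (screen px, origin top-left) within one oculomotor
event follows a stationary Ornstein–Uhlenbeck diffusion

    dx(t) = B (μ − x(t)) dt + Γ dW(t),

with a symmetric drift matrix `B` (all eigenvalues positive; units
1/sample), a symmetric positive-definite diffusion amplitude `Γ`
(px/√sample), and an attractor `μ`. The process is state-switching across a
scan path: fixations revert to a local centre, saccades are pulled toward
their landing point, each with its own `(B, Γ)`. `Γ` multiplies the Wiener
increment, so the instantaneous noise covariance is `Γ² = Γ Γᵀ`; this
convention makes the stationary covariance `D` exactly the solution of the
continuous Lyapunov equation

    B D + D Bᵀ = Γ²,

which reduces componentwise to `D = Γ²/(2B)` whenever `B` and `Γ` commute
(e.g. both diagonal). The unit-step transition law is Gaussian,

    x(t+1) | x(t) ~ N( μ + e^{−B}(x(t) − μ),  Ψ ),   Ψ = D − e^{−B} D e^{−Bᵀ},

and, because `B` is symmetric, every matrix function is evaluated in its
eigenbasis: with `B = Q Λ Qᵀ`, the rotated stationary covariance is
`D'_{ab} = (Qᵀ Γ² Q)_{ab}/(λ_a + λ_b)` and
`Ψ'_{ab} = D'_{ab}(1 − e^{−(λ_a+λ_b)Δt})` — closed forms that keep a
likelihood evaluation at ~30 µs for a 1000-sample slice. `Ψ` is
symmetrised and eigenvalue-clipped at zero (tolerance 1e−12); inside the
likelihood a configurable jitter (default 1e−9 px²) is added to its
diagonal when it is numerically singular.

Time is measured in samples: the recorded sampling rate (1000 Hz in the
target setting) only documents units, the model always uses Δt = 1.

## Event parsing

The default parser is velocity-threshold (I-VT-style): per-sample velocity
by centred finite differences, the velocity *vectors* boxcar-smoothed over
5 samples, then thresholded on the norm (default 0.8 px/sample at
1000 Hz). Smoothing the vectors rather than the scalar speeds is
deliberate: zero-mean fixational noise of amplitude Γ averages down to
≈ 0.3·Γ px/sample while coherent saccadic drift is unaffected, so the two
regimes stay separable even for noisy fixations. Runs shorter than a
per-kind minimum (40 samples for fixations, 10 for saccades) are flipped
into the neighbouring kind and coalesced until all runs qualify; output
events therefore alternate and tile the trajectory without overlap
(half-open 0-based spans).

Attractors are attached per the functional definitions: fixation μ is the
slice centroid, saccade μ its final (landing) sample. An adapter accepts
per-sample labels from any external event classifier; `other` labels
(smooth pursuit, post-saccadic oscillations) are dropped, and degenerate
single-sample runs are discarded with a warning. Events with fewer than
`min_transitions` (default 5) transitions are excluded from inference and
counted in the pipeline log.

## Priors and inference

`B` and `Γ` are each parameterised as `M = diag(s) R diag(s)` with
componentwise scales `s` and a 2×2 correlation `R` — i.e.
`M_ii = s_i²`, `M_ij = ρ s_i s_j` — which enforces symmetry and positive
eigenvalues for any `s > 0`, `|ρ| < 1`. Priors: LKJ(η = 2) on each
correlation (density ∝ (1−ρ²)^{η−1}) and half-normal scales, sd 1.0 for
`B` (so `B_ii` has prior mass up to ≈ 4/sample) and 5.0 for `Γ` (diffusion
amplitudes up to ≈ 100 px/√sample) — weakly informative at the data's unit
scale. Inference runs in the unconstrained space
`z = (log s₁, log s₂, atanh ρ) × 2` (6 dimensions, clipped to ±12) with
the transform Jacobians included; the attractor μ is fixed by segmentation
and excluded from the parameter set, and the likelihood is the Markov
product of unit-step transition densities over the slice.

Two approximations sit behind one contract:

* **`map_laplace`** (default): L-BFGS-B maximisation of the log posterior
  from a moment-based start (per-dimension AR(1) fits give `b = −log a` and
  `Γ² = 2bD`), then a Gaussian approximation from the finite-difference
  Hessian at the mode. Posterior draws (default 1000) are taken in z-space
  and pushed through the transform. Curvature eigenvalues are floored at
  0.5 so that directions the data leave flat fall back to roughly the
  prior's width instead of an unbounded Gaussian — without the floor,
  degenerate short events (e.g. a near-deterministic saccade slice whose
  attractor is its own final sample) produce draw clouds clipped at the
  transform bounds and absurd pushed-forward means. A non-positive-definite
  Hessian or optimiser failure sets the summary's convergence flag.
  ~0.05 s per 1000-sample event.
* **`vi`**: mean-field Gaussian variational approximation optimised by
  Adam (lr 0.05) on the reparameterised evidence lower bound, one
  Monte-Carlo sample per step and central finite-difference gradients of
  the joint density (cheap in 6 dimensions). Default budget 5000
  iterations with early stopping when the smoothed objective plateaus for
  1000 steps; the flag is raised if the budget ends while still improving.
  ~5 s per 1000-sample event; posterior means agree with `map_laplace`
  within a few percent on well-informed events.

Summaries per free component (`B_ii, B_ij, B_jj, Γ_ii, Γ_ij, Γ_jj`): the
draw mean and the narrowest contiguous interval holding the configured
mass (HDI, default 0.94; cross-checked against arviz in the tests). The
feature-facing uncertainty scalar is the HDI *width*. Simulation-based
calibration over prior draws measures ≈ 88% pooled coverage for the
nominal 94% HDIs — the expected mild optimism of Gaussian approximations
on skewed posteriors; the acceptance checks budget for it.

## Descriptors, identification, evaluation

The event descriptor interleaves mean and HDI width in a fixed order
(12 components). A scan-path descriptor is the componentwise mean of its
fixation descriptors concatenated with the mean of its saccade
descriptors (24 components, fixation block first); an absent kind leaves a
NaN sentinel block with zero count, and subject summaries average over the
scan paths where each block is present.

Identification trains one RBF-kernel SVM per enrolled subject and per
event kind (one-vs-rest margins, C = 1, bandwidth by the median heuristic
on z-scored training features; standardisation is fitted on training folds
only). A probe trajectory's per-kind decision vectors are averaged and the
two averages summed; a missing kind contributes a zero vector, neutral
under the additive fusion. Ties at the argmax break by class-list order
and are logged. Models serialise to JSON (class list, standardiser,
kernel spec, support vectors, dual weights); decisions are computed
directly from those arrays, so a reloaded model scores identically.

Cross-validation splits at the scan-path level, stratified by subject —
events within a trajectory are dependent, and splitting them across folds
would leak identity. Metrics: argmax accuracy and macro F1; EER and AUC
from the micro-averaged one-vs-rest pooling (every (probe, class) pair a
binary instance, EER linearly interpolated at the FAR = FRR crossing);
CMS[k] as the fraction of probes whose true class ranks in the top k. The
correlation analyses report the between-subject correlation matrix of
summary vectors and the intra- (same subject, different stimuli) versus
inter-subject ensembles of scan-path descriptor correlations with
Gaussian KDEs (Scott bandwidth); zero-variance vectors are excluded with a
log entry. The label-shuffle null control averages 10 independent
shuffles: a single shuffle's AUC on 60 probes has a standard error of
≈ 0.04, wider than the effect being tested, while 10 shuffles estimate the
null mean to ≈ 0.013.

## Synthetic cohorts

The simulator emulates the target acquisition setting: 2-second scan
paths at 1000 Hz on a 1024×768 px screen. A scan path starts with a
fixation at a uniform on-screen point; each saccade aims at a fresh
uniform target (50 px inset, trajectories never clipped — clipping would
distort the O-U statistics), and the next fixation reverts to the
saccade's landing point, so trajectories are continuous. Durations:
log-normal fixations (mean 250, sd 80 samples), uniform 20–60-sample
saccades. Base regimes — fixation `B = 0.03 I`, `Γ = 0.5 I`; saccade
`B = 0.2 I`, `Γ = 2 I` — give ≈ 2 px fixational dispersion, saccades that
land within a few px of their target, and a clear velocity contrast.
Event spans are contiguous half-open intervals whose first sample is
produced by the preceding event.

Cohorts draw one parameter set per subject: diagonal entries log-normal
around the base with log-sd `0.4 × separation`, correlations
`tanh(N(0, 0.5 × separation))` clipped to ±0.8. `separation = 0` makes
subjects identical; 1.0 is the default; 1.5 is used as the
"high-separation" benchmark condition. Problem sizes in the tests and the
acceptance script — 5 subjects × 12 scan paths, ≈ 900 events inferred in
`map_laplace` mode — keep a full benchmark run under a minute.

What the generator does *not* emulate: smooth pursuit, post-saccadic
oscillations, blinks and tracker dropout, measurement noise distinct from
the process noise, saliency-driven target choice, and any heavy-tailed
(Lévy-like) increment structure. Passing benchmarks on this cohort
therefore demonstrate that the pipeline recovers and discriminates
switching O-U dynamics — the model class itself — not that real gaze is
O-U; on real recordings the descriptors inherit whatever misfit the model
has there.

## Known limitations

* The Laplace and mean-field approximations under-cover slightly
  (≈ 88% for nominal 94% intervals) and mean-field VI additionally
  underestimates posterior correlations between components.
* Drift (`B`) is weakly informed by short events — per-event relative
  errors of tens of percent are normal at fixation-like time constants —
  so identification leans more on the diffusion entries; HDI widths carry
  that uncertainty into the feature vector.
* The velocity parser is a deliberate simplification of segmented-
  regression/HMM event classifiers; external labels can be imported when
  higher-fidelity parsing matters.
* Verification protocols (enrol/probe with impostors) are out of scope;
  EER here is computed from the identification score matrix.
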