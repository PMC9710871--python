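# Methods

## The model

A cell's expression state x ∈ ℝ₊ᴳ (normalized spliced counts over G
"velocity genes") and its RNA velocity v = ∂x/∂t are treated as a sample
from an autonomous dynamical system ∂x/∂t = f(x).  The field f is learned
from the (x, v) pairs of all cells and then integrated as an initial value
problem, so the package's claims are about *simulated* dynamics: everything
downstream (criticality, perturbation screens, retrograde ensembles) is a
function of trajectories of the learned field, not of the raw data alone.

## Vector-field learning

f is a variational autoencoder mapping x to v: encoder
x → relu(W₁x+b₁) → (μ, log σ²) ∈ ℝ¹⁶, decoder z → relu(W₄z+b₄) → v̂, with a
64-unit intermediate layer on each side.  During training
z = μ + ε·σ (reparameterization, ε ~ N(0, I)); at inference z = μ, making
the field deterministic — a requirement for reproducible ODE integration.
The loss is

    MSE(v, v̂) + β · KL(q(z|x) ‖ N(0, I)) + λ · Σ_layers mean|activation|

minimized with Adam.  Defaults: learning rate 1e-5, batch size 32,
λ = 1e-6, early stopping when the validation loss (10% of cells, split once
per run) fails to improve for 3 consecutive epochs, with the
best-validation-epoch weights restored.  `max_epochs` defaults to 1000; at
the small default learning rate the early-stopping criterion, not the
epoch cap, normally ends training.

**KL balance (β).**  The reconstruction term is a *mean* over genes and the
KL term a mean over latent dimensions, and β defaults to 1e-3.  With a
per-gene-mean MSE on data of order-1 normalized counts, a unit-weight KL
dominates the objective and collapses the posterior: the decoder then
predicts a near-constant velocity and cannot outperform even a linear
baseline (measured on the toggle-switch conditions: reconstruction plateau
≈ 0.046 versus 0.035 for ordinary least squares, while an unregularized fit
reaches ≈ 0.030).  β = 1e-3 keeps a proper variational bottleneck — the
posterior variance head stays active and sampling mode remains meaningful —
without starving the regression.  β is exposed (`VAEArchitecture.kl_weight`)
for data on other scales.

**Denoising mode.**  Optionally each training input is corrupted as x + ε
with εᵢ ~ Exponential(scale = r·SDᵢ) per gene (`denoise_noise_rate` r; off
by default, r ≈ 0.1–0.2 is a reasonable setting).  The one-sided positive
noise emulates count inflation and widens the input region where the field
is trained, improving extrapolation off the manifold; the test suite
verifies the robustness gain directly.

**Baseline.**  `fit_linear_baseline` is the ordinary-least-squares
velocity predictor (with intercept) on the same training split — the
simplest competing vector-field model and the reference the VAE must beat
on held-out MSE.

## Integration

One *solver step* is a forward-Euler update x ← x + dt·s·f(x) with
dt = `step_time` (default 1) and velocity scaling s (default 0.65, the
calibration between velocity units and the unit time step).  A recorded
*discrete step* comprises `intermediate_steps` (default 5) solver steps.
With `method="rk23"` or `"dop853"` the same time horizon per discrete step
is integrated by the scipy adaptive solver (tolerances rtol 1e-3 /
atol 1e-6, configurable); the Euler trajectory is the reference the
adaptive solvers converge to, and DOP853 on an analytic linear field
reproduces the matrix-exponential solution to ≤ 1e-4 relative error.

Negative components are clipped to zero after each discrete step
(expression cannot be negative); the clip has an off-switch used by the
solver-verification tests.  Retrograde integration negates the right-hand
side.

**Anchoring.**  After every discrete step the state can be snapped to the
mean expression profile of its `anchor_k` = 5 nearest reference cells in
the top-`pca_dims` = 30 principal components of the reference data
(deterministic full-SVD PCA; equidistant ties broken by lowest cell
index).  This suppresses dead-reckoning error accumulation and acts as a
boundary condition: a state that leaves the manifold is pulled back to it.
Anchored states are convex combinations of observed cells, which also
averages measurement noise.  Retrograde ensembles anchor by default
because time-reversed dynamics are unstable around forward-stable
attractors — unanchored backward trajectories leave the data manifold
within a few steps, and on sparse reference data (≲ 1500 cells here)
anchored backward trajectories can instead stall in an anchor fixed point;
a denser reference resolves this.

**Step budget.**  The number of solver steps needed to reach a terminal
state is estimated per gene as its ±2 SD expression range (width 4·SD)
divided by its mean |velocity|, excluding zero-velocity genes; the budget
is the 95th–99th percentile of these counts, i.e. enough steps for a 2 SD
change in at least that fraction of genes.  The "±2 SD" reading of the
range is a documented choice; it only rescales the budget and the
percentile is exposed.

## Criticality

Expression vectors are mapped to the probability simplex with a pseudocount
((x + 1e-8) / Σ(x + 1e-8)) before any information measure — raw normalized
counts neither sum to one nor avoid zeros, and KL is undefined otherwise.
All quantities are in nats.  StemID entropy is −Σ pᵢ log pᵢ of a single
state (bounded by log G, attained by the uniform state).  The CCI of a cell
sums KL(p_{t+1} ‖ p_t) over T = 35 recorded transitions of its simulated
forward trajectory (anchored by default, so trajectories settle on the
manifold).  The upper summation index is read as T transitions
(t = 0 … T−1), which is what a T-step trajectory supports.  Absolute CCI
values depend on the pseudocount and normalization; the supported contract
is the *ranking* (e.g. saddle cells above attractor cells), which is what
the tests assert.

## Fate classification, sampling, perturbation

The fate model projects states onto the top 30 PCs of the labeled
reference and votes over the K = 30 nearest cells; ties go to the smallest
label code.  Out-of-sample cells of a type are sampled as
median ± Exponential(scale = per-gene within-type SD) with an independent
fair-coin sign per gene per cell (the sign mechanism is unstated upstream;
a fair coin is the symmetric choice), clipped at zero.

The driver screen: (1) progenitor cells are integrated to the estimated
step budget with anchoring and classified, giving baseline fate counts;
(2) genes are ranked by Wilcoxon rank-sum between the *initial* states of
the two realized-fate groups with Bonferroni correction, and the top
`top_n_de` genes higher in the target-fate group are kept (cells
classified as neither fate are excluded from the grouping); (3) each
candidate is clamped to its dataset-wide 99th-percentile expression —
re-applied after every solver step and anchoring event, i.e. a sustained
activation, not a one-shot bump — trajectories re-run, and a one-sided
binomial test compares the target-fate count against the baseline
proportion (a 50:50 null is available via `null_proportion="half"`).
Driver flag at p < 0.05.  Because baseline and perturbed runs share
initial states, and because clamping any gene shifts anchor neighborhoods,
genes merely *correlated* with the fate can reach borderline significance;
the planted-driver effect in the test system is orders of magnitude
stronger, and a zero-influence gene's flag rate is verified to stay at the
nominal level over repeated screens.

## Coexpression and enrichment

Retrograde ensembles pool all recorded (anchored) states — not solver
micro-steps — of 50 trajectories integrated backwards for 15 discrete × 5
intermediate steps from sampled terminal-type cells.  Pearson correlation
over the pooled states is biclustered by average-linkage hierarchical
clustering on distance 1 − r (ward/complete available) cut at 3 clusters.
Enrichment per cluster × gene set is a one-sided Fisher exact test over a
user-supplied background, BH-corrected jointly across all cluster × set
tests (the joint family is the conservative reading of an ambiguous
protocol); per set the most significant cluster is reported, and
`compare_sources` tabulates best-q side by side for static-cell versus
retrograde-dynamic modules.  Gene sets are read from GMT files; ontology
download or propagation is out of scope.

## The synthetic testbed

`make_toggle_switch` builds dx₁/dt = a/(1+x₂ʰ) − x₁ (symmetrically for x₂)
with a = 2, h = 4: two stable attractors at ≈ (2.00, 0.12) / (0.12, 2.00)
and a saddle at exactly (1, 1) (the diagonal fixed point solves
x⁵ + x − 2 = 0).  Bystander genes split into thirds: responders relaxing
toward wⱼ·x₁ or wⱼ·x₂ (wⱼ ~ U(0.8, 1.2); a planted coexpression module and
realistic fate-correlated passengers) and null genes relaxing to private
constants (negative controls with provably zero influence on the core).
All fixed points are verified to machine accuracy at construction.

`sample_cells` scatters initial states across the basin boundary
(core ~ U(0.05, 2.2)², bystanders ~ U(0, 2)), integrates the true field for
U(0, 8) time units (fixed-step RK4, dt = 0.02) to populate the manifold,
records v = f(x) at the landing state, then corrupts the *observed*
expression with multiplicative log-normal noise (σ = 0.15) and Bernoulli
dropout (rate 0.05).  These defaults emulate data that has already passed
HVG selection and kNN moment smoothing — the regime velocity estimates
live in — rather than raw droplet sparsity; library-size effects, batch
structure and spliced/unspliced kinetics are deliberately not modeled, so
passing tests demonstrate correct recovery of known dynamics under
moderate observation noise, not robustness to every artifact of real
scRNA-seq.  Cells within core distance 0.5 of the saddle are labeled
progenitors; every cell carries its ground-truth fate (noiseless
integration of its clean state) and saddle distance in `obs_meta`.
`true_terminal` is the high-accuracy oracle (DOP853, rtol 1e-10).

## Problem sizes and numerical choices

The test suite and the acceptance script run the study conditions at 2000
cells × 20 genes with 5 (tests) or 3 (script) seeds — sizes chosen so the
full pipeline (training through screens) completes in minutes on one CPU
while leaving clear statistical margins; fate-recovery agreement is pooled
across seeds because each seed holds out only ~25 progenitors.  Fate
evaluation compares the pipeline's prediction from a cell's *observed*
state with the oracle applied to the same observed state, so measurement
noise in the initial condition does not count against the learned
dynamics.  PCA uses `pca_dims = n_genes − 1` when the feature space is
smaller than the default 30 (the projection warns and reduces
automatically).  All randomness flows through seeded `numpy` generators;
reruns are bit-identical, including CLI outputs.

## Known limitations

- The learned field is only as good as the upstream velocity estimates; no
  attempt is made to re-estimate or correct velocities.
- Time is in solver units; the velocity scale (0.65) calibrates step size,
  not wall-clock developmental time.
- Near a separatrix, small field errors flip predicted fates; accuracy
  there is intrinsically limited by how well the data constrain f around
  the saddle.
- The binomial driver test treats trajectories as independent and the
  baseline proportion as known; correlated passenger genes can reach
  borderline significance (see above).
- Anchoring constrains simulation to the observed manifold: it cannot
  simulate states the experiment never sampled, and on sparse references
  it can stall retrograde trajectories.
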