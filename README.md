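# velonode

Neural-ODE simulation of single-cell trajectories from RNA velocity.

Single-cell RNA sequencing captures each cell's expression state **x** once,
but spliced/unspliced transcript ratios also yield the instantaneous rate of
change ∂x/∂t (RNA velocity).  The (state, velocity) pairs of all cells are
samples of a dynamical system; `velonode` learns its vector field

    ∂x/∂t = f(x)

with a denoising variational autoencoder (encoder 64 → latent 16 → decoder
64, relu, L1 λ = 10⁻⁶ on activations, Adam at learning rate 10⁻⁵ with batch
size 32 and patience-3 early stopping) and integrates it as an ordinary
differential equation (forward Euler x_{t+1} = x_t + s·f(x_t) with velocity
scaling s = 0.65, or adaptive RK23/DOP853) to simulate where any cell —
including hypothetical, out-of-sample ones — is heading, or where it came
from (retrograde integration, x_{t−1} = x_t − f(x_t)).  Accumulated
prediction error ("dead reckoning") is suppressed by periodically anchoring
the simulated state to the mean of its K = 5 nearest reference cells in
top-30-PC space.

On top of simulated trajectories the package provides:

- **Cell criticality index (CCI)** — cumulative KL divergence between
  consecutive expression distributions over T = 35 simulated steps,
  CCI(x) = Σₜ KL(x_{t+1} ‖ x_t).  High CCI marks unstable, fate-committing
  states; contrasted with StemID entropy −Σᵢ xᵢ log xᵢ ("kinetic" vs
  "potential" instability).
- **In-silico driver screens** — progenitors are evolved to terminal states
  and classified (KNN, K = 30, on top-30 PCs); Wilcoxon/Bonferroni DE genes
  between realized fates are clamped one at a time to their 99th-percentile
  expression, and a one-sided binomial test calls genes whose sustained
  activation significantly shifts the terminal-fate ratio.
- **Trajectory-denoised coexpression** — ensembles of retrograde
  trajectories from a terminal cell type yield gene-gene correlations far
  less contaminated by per-cell measurement noise than static cells;
  modules from hierarchical biclustering are scored against GMT gene sets
  (Fisher exact + Benjamini-Hochberg).

The package is aimed at computational biologists with a cell-by-gene matrix
of normalized spliced counts, a matching velocity matrix (e.g. from scVelo),
and cell-type labels, in h5ad, loom, or MTX form.  A built-in synthetic
module (`make_toggle_switch` / `sample_cells`) generates ground-truth
bistable dynamics — two mutually repressing Hill-kinetics genes plus
responder and null bystanders — with scRNA-seq-like noise, so every claim
the toolkit makes can be tested without downloading anything.

## Worked example

`examples/01_train_and_simulate.py` builds a noisy 1200-cell toggle-switch
dataset, trains the field, and simulates one progenitor forward:

```
dataset: 1200 cells x 20 genes, labels ['FateA', 'FateB', 'Progenitor']
trained 69 epochs; best validation loss 0.0432
core genes start [0.86 1.55] -> end [0.14 2.  ]
terminal fate: FateB (probabilities {'FateA': 0.0, 'FateB': 1.0, 'Progenitor': 0.0})
```

The progenitor began near the fate-decision saddle with the second core gene
slightly dominant (1.55 vs 0.86); integrating the learned dynamics with
anchoring carries it to the (0.12, 2.0) attractor, and the KNN fate model
classifies the terminal state as FateB with probability 1.0 — matching the
ground-truth flow of the underlying system.  The remaining examples
demonstrate criticality scoring, the driver screen, and retrograde
coexpression; each prints a short interpretation with its numbers.

A thin CLI mirrors the library:

```sh
vnode synth --cells 2000 --seed 0 --out ds.h5ad
vnode train --data ds.h5ad --seed 0 --out field.json
vnode simulate --field field.json --data ds.h5ad --init cell:0 --steps 12 --out traj.csv
vnode cci --field field.json --data ds.h5ad --steps 35 --out cci.csv
vnode perturb --field field.json --data ds.h5ad --progenitor Progenitor --fates FateA,FateB --out report.json
vnode coexpr --field field.json --data ds.h5ad --terminal FateA --gene-sets examples/data/toggle_modules.gmt --out coexpr/
```

Identical seeds and configuration produce byte-identical outputs.

## Layout

- `src/velonode/` — `data` (I/O and validation), `vae` (vector-field
  learning), `trajectory` (ODE integration, anchoring, step budgets),
  `criticality` (CCI / StemID), `fate` (classification, sampling,
  perturbation screens), `coexpression` (retrograde ensembles, biclustering,
  enrichment), `synthetic` (ground-truth systems), `cli`, `config`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
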