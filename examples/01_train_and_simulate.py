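"""Learn a vector field from (expression, velocity) pairs and simulate a
cell's future.

Builds a small toggle-switch dataset with scRNA-seq-like noise, trains the
denoising-VAE vector field, then integrates one progenitor cell forward in
time with reference-cell anchoring and classifies its terminal state.
"""

import numpy as np

import velonode as vn

system = vn.make_toggle_switch(n_bystander_genes=18, seed=0)
ds = vn.sample_cells(system, 1200, seed=0)
print(f"dataset: {ds.n_cells} cells x {ds.n_genes} genes, "
      f"labels {ds.label_set}")

field = vn.train_field(ds, vn.VAEArchitecture(input_dim=ds.n_genes),
                       vn.TrainConfig(seed=0))
h = field.history
print(f"trained {len(h['val_loss'])} epochs; "
      f"best validation loss {h['val_loss'][h['best_epoch']]:.4f}")

# a progenitor cell near the fate decision point
prog_idx = int(np.flatnonzero(ds.cells_with_label("Progenitor"))[0])
x0 = ds.expression[prog_idx]
spec = vn.IntegratorSpec(anchor=True, n_steps=12, intermediate_steps=5,
                         pca_dims=ds.n_genes - 1)
traj = vn.integrate(field, x0, spec, reference=ds)

model = vn.fit_fate_model(ds, pca_dims=ds.n_genes - 1, k=30)
fate, proba = vn.classify_state(model, traj.states[-1])
print(f"core genes start {x0[:2].round(2)} -> end "
      f"{traj.states[-1][:2].round(2)}")
print(f"terminal fate: {fate} "
      f"(probabilities {dict(zip(model.classes, proba.round(2)))})")
print("The trajectory follows the learned dynamics along the data manifold;"
      " the terminal core-gene pattern shows which attractor the cell"
      " committed to.")
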