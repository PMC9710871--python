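"""Trajectory-denoised coexpression modules from retrograde ensembles.

Hypothetical terminal cells are integrated backwards in time under the
learned dynamics; gene-gene correlations over the pooled simulated states
are far less contaminated by per-cell measurement noise than correlations
over the observed (static) cells.  Modules are found by hierarchical
biclustering and scored against bundled gene sets with Fisher exact tests.
"""

import os

import numpy as np

import velonode as vn

system = vn.make_toggle_switch(18, seed=0)
ds = vn.sample_cells(system, 2000, seed=0)
field = vn.train_field(ds, vn.VAEArchitecture(input_dim=ds.n_genes),
                       vn.TrainConfig(seed=0))

# retrograde ensemble from the FateA terminal type: 50 cells x 16 states
ensemble = vn.retrograde_ensemble(field, ds, "FateA", n_cells=50, seed=0)
R_dyn = vn.correlation_matrix(ensemble)
R_static = vn.correlation_matrix(ds.expression[ds.cells_with_label("FateA")])

module = [ds.gene_names.index(g) for g in system.module_a_genes]
iu = np.triu_indices(len(module), 1)
print(f"planted module {system.module_a_genes}:")
print(f"  mean |r| from static noisy cells:      "
      f"{np.abs(R_static[np.ix_(module, module)][iu]).mean():.3f}")
print(f"  mean |r| from retrograde trajectories: "
      f"{np.abs(R_dyn[np.ix_(module, module)][iu]).mean():.3f}")

clusters_dyn = vn.bicluster(R_dyn, ds.gene_names)
clusters_static = vn.bicluster(R_static, ds.gene_names)
sets = vn.read_gmt(os.path.join(os.path.dirname(__file__), "data",
                                "toggle_modules.gmt"))
comparison = vn.compare_sources(
    vn.CoexpressionResult(R_static, clusters_static, "static_cells",
                          0, ds.gene_names),
    vn.CoexpressionResult(R_dyn, clusters_dyn, "retrograde_dynamic",
                          len(ensemble), ds.gene_names),
    sets, ds.gene_names,
)
print(comparison.to_string(index=False))
print("The retrograde ensemble roughly triples the within-module"
      " correlation of the planted module. The enrichment table compares"
      " the best BH-adjusted q per gene set between the two sources"
      " (positive log10_q_ratio = dynamic more enriched); on this small"
      " single-branch system the biclustering of the two matrices can cut"
      " the modules differently, so the q comparison is reported, not"
      " guaranteed, output.")
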