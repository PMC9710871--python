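"""In-silico perturbation screen for fate-determining driver genes.

Progenitor cells are evolved under the learned dynamics and classified;
genes differentially expressed between the initial states of the two
realized fates are clamped, one at a time, to their 99th-percentile
expression, and a one-sided binomial test asks whether the target-fate
proportion increased over baseline.
"""

import velonode as vn

system = vn.make_toggle_switch(18, seed=0)
ds = vn.sample_cells(system, 1500, seed=0)
field = vn.train_field(ds, vn.VAEArchitecture(input_dim=ds.n_genes),
                       vn.TrainConfig(seed=0))

report = vn.run_perturbation_study(
    field, ds, "Progenitor", ("FateA", "FateB"), top_n_de=10,
    spec=vn.IntegratorSpec(anchor=True, pca_dims=ds.n_genes - 1), seed=0,
)
print(f"baseline terminal counts from {report.n_initial} progenitors: "
      f"{report.baseline_counts}")
print("top DE genes associated with FateA:")
print(report.de_table.sort_values("p_adjusted").head(5).to_string(index=False))
print(f"driver genes (binomial p < 0.05): {report.driver_genes}")
drv = report.per_gene["core_a"]
print(f"clamping the true driver 'core_a': {drv['counts']} "
      f"(p = {drv['p_value']:.2e})")
print("The planted fate-determining gene shifts essentially every"
      " progenitor to FateA with overwhelming significance; passenger"
      " genes that merely correlate with the fate can reach borderline"
      " p-values, so driver calls should be read alongside effect sizes.")
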