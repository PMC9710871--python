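"""Terminal cell-fate classification and the in-silico perturbation screen.

A fate model projects any expression state onto the top principal components
of the reference data (default 30 PCs) and votes over the K nearest labeled
training cells (default K=30), yielding a cell-type probability vector.

The driver screen runs in three stages: (1) progenitor states evolve under
the learned dynamics to their terminal step budget and are classified,
giving baseline fate counts; (2) genes differentially expressed between the
*initial* states of cells that realized the target fate versus the other
fate are found (Wilcoxon rank-sum, Bonferroni), and the top genes higher in
the target-fate group are selected; (3) each candidate gene in turn is
clamped to its dataset-wide 99th-percentile expression in every progenitor —
and held there through every integration step — the trajectories re-run and
re-classified, and a one-sided binomial test asks whether the target-fate
count increased significantly over baseline.  Genes passing P < alpha are
called developmental drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .trajectory import (
    GeneClamp,
    IntegratorSpec,
    ReferenceProjection,
    estimate_step_budget,
    fit_reference_projection,
    integrate_batch,
)

__all__ = [
    "FateModel",
    "PerturbationReport",
    "fit_fate_model",
    "classify_state",
    "classify_states",
    "sample_out_of_sample",
    "perturb_gene",
    "run_perturbation_study",
]


@dataclass
class FateModel:
    """PCA projection + KNN voter mapping any state to cell-type
    probabilities.  Label classes are sorted; ties in the vote are broken by
    the smallest label code (argmax returns the first maximum)."""

    projection: ReferenceProjection
    knn_k: int
    classes: list[str]
    training_codes: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("states must be finite")
        nn = self.projection.nearest(X, self.knn_k)
        votes = self.training_codes[nn]  # (m, k)
        proba = np.zeros((len(X), len(self.classes)))
        for c in range(len(self.classes)):
            proba[:, c] = (votes == c).mean(axis=1)
        return proba

    def predict(self, X: np.ndarray) -> list[str]:
        proba = self.predict_proba(X)
        return [self.classes[i] for i in proba.argmax(axis=1)]


def fit_fate_model(ds: Dataset, pca_dims: int = 30, k: int = 30) -> FateModel:
    """Fit the nonparametric fate classifier on the labeled reference data."""
    if k > ds.n_cells:
        raise ValueError(f"k={k} exceeds n_cells={ds.n_cells}")
    projection = fit_reference_projection(ds, pca_dims)
    classes = ds.label_set
    code_of = {c: i for i, c in enumerate(classes)}
    codes = np.array([code_of[lab] for lab in ds.cell_labels])
    return FateModel(projection, k, classes, codes)


def classify_state(model: FateModel, x: np.ndarray) -> tuple[str, np.ndarray]:
    """(most probable label, probability vector over model.classes)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1 and x.size != model.projection.reference_expression.shape[1]:
        raise ValueError(
            f"expected {model.projection.reference_expression.shape[1]} genes, "
            f"got {x.size}"
        )
    proba = model.predict_proba(x)[0]
    return model.classes[int(proba.argmax())], proba


def classify_states(model: FateModel, X: np.ndarray) -> list[str]:
    """Vectorized :func:`classify_state` (labels only)."""
    return model.predict(X)


def sample_out_of_sample(ds: Dataset, cell_type: str, n: int,
                         seed: int = 0) -> np.ndarray:
    """Sample hypothetical cells of a given type.

    Each sample is the per-gene median expression of the type, moved up or
    down (independent fair coin per gene per cell) by an exponentially
    distributed amount with scale equal to the gene's within-type SD, then
    clipped at zero.  Zero-variance genes reproduce the median exactly.
    """
    mask = ds.cells_with_label(cell_type)
    if mask.sum() < 2:
        raise ValueError(
            f"cell type {cell_type!r} absent or has fewer than 2 cells"
        )
    X = ds.expression[mask]
    median = np.median(X, axis=0)
    sd = X.std(axis=0, ddof=1)
    rng = np.random.default_rng(seed)
    signs = np.where(rng.random((n, ds.n_genes)) < 0.5, -1.0, 1.0)
    magnitude = rng.exponential(1.0, size=(n, ds.n_genes)) * sd
    return np.maximum(median + signs * magnitude, 0.0)


def perturb_gene(states: np.ndarray, ds: Dataset,
                 gene: str) -> tuple[np.ndarray, GeneClamp]:
    """Activate one gene: set its column to the dataset-wide 99th-percentile
    expression and return a clamp directive that integration re-applies after
    every step and anchoring event."""
    gi = ds.gene_index(gene)
    value = float(np.percentile(ds.expression[:, gi], 99))
    clamp = GeneClamp(gi, value)
    out = np.atleast_2d(np.asarray(states, dtype=float)).copy()
    return clamp.apply(out), clamp


@dataclass
class PerturbationReport:
    baseline_counts: dict[str, int]
    per_gene: dict[str, dict]        # gene -> {counts, p_value, driver}
    de_table: pd.DataFrame
    n_initial: int
    initial_source: str
    config: dict

    @property
    def driver_genes(self) -> list[str]:
        return [g for g, r in self.per_gene.items() if r["driver"]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, r in self.per_gene.items():
            row = {"gene": gene, "p_value": r["p_value"],
                   "driver": r["driver"]}
            for lab, c in r["counts"].items():
                row[f"count_{lab}"] = c
            rows.append(row)
        return pd.DataFrame(rows)


def _wilcoxon_de(X_target: np.ndarray, X_other: np.ndarray,
                 genes: list[str]) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum between two groups of initial states, with
    Bonferroni correction; effect > 0 means higher in the target group."""
    from statsmodels.stats.multitest import multipletests

    p = np.ones(len(genes))
    effect = np.zeros(len(genes))
    for j in range(len(genes)):
        a, b = X_target[:, j], X_other[:, j]
        effect[j] = a.mean() - b.mean()
        if np.ptp(np.concatenate([a, b])) == 0:
            p[j] = 1.0
            continue
        p[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    adj = multipletests(p, method="bonferroni")[1]
    return pd.DataFrame({"gene": genes, "effect": effect,
                         "p_value": p, "p_adjusted": adj})


def run_perturbation_study(
    field,
    ds: Dataset,
    progenitor_label: str,
    fate_labels: tuple[str, str],
    top_n_de: int = 20,
    spec: IntegratorSpec | None = None,
    model: FateModel | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    null_proportion: str = "baseline",   # or "half"
    step_percentile: float = 95.0,
    max_step_cap: int | None = None,
) -> PerturbationReport:
    """Three-stage in-silico driver screen (see module docstring).

    ``fate_labels`` is ``(target, other)``; drivers are genes whose sustained
    activation significantly increases the target-fate proportion.  Cells
    classified as neither fate count against the target proportion but are
    excluded from the DE grouping.
    """
    target, other = fate_labels
    for lab in (progenitor_label, target, other):
        if lab not in ds.label_set:
            raise ValueError(f"label {lab!r} not present in dataset")
    if model is None:
        model = fit_fate_model(ds)
    if spec is None:
        spec = IntegratorSpec(anchor=True)
    budget = estimate_step_budget(ds, step_percentile)
    # budget counts solver (intermediate) steps; trajectories record one
    # state per `intermediate_steps` of them
    n_steps = max(1, -(-budget.max_steps // spec.intermediate_steps))
    if max_step_cap is not None:
        n_steps = min(n_steps, max_step_cap)
    spec = replace(spec, n_steps=n_steps)
    projection = model.projection

    prog_mask = ds.cells_with_label(progenitor_label)
    X0 = ds.expression[prog_mask]
    n = len(X0)

    # stage 1: baseline evolution and classification
    states, _, _, diag = integrate_batch(field, X0, spec, projection,
                                         None, "forward")
    terminals = states[-1]
    baseline_labels = np.array(classify_states(model, terminals))
    baseline_counts = {lab: int((baseline_labels == lab).sum())
                       for lab in model.classes}
    k0 = baseline_counts.get(target, 0)
    if k0 == 0 or baseline_counts.get(other, 0) == 0:
        missing = target if k0 == 0 else other
        raise ValueError(
            f"fate {missing!r} never reached at baseline "
            f"(counts: {baseline_counts}); cannot group initial states for DE"
        )

    # stage 2: DE on initial states grouped by realized fate
    de = _wilcoxon_de(X0[baseline_labels == target],
                      X0[baseline_labels == other], ds.gene_names)
    cand = de[de["effect"] > 0].sort_values(
        ["p_adjusted", "p_value"], kind="stable"
    )
    candidates = cand["gene"].head(top_n_de).tolist()

    # stage 3: clamp-perturb each candidate and re-screen
    p0 = k0 / n if null_proportion == "baseline" else 0.5
    per_gene: dict[str, dict] = {}
    for gene in candidates:
        Xp, clamp = perturb_gene(X0, ds, gene)
        st, _, _, _ = integrate_batch(field, Xp, spec, projection,
                                      clamp, "forward")
        labels = np.array(classify_states(model, st[-1]))
        counts = {lab: int((labels == lab).sum()) for lab in model.classes}
        k = counts.get(target, 0)
        pval = stats.binomtest(k, n, p0, alternative="greater").pvalue
        per_gene[gene] = {"counts": counts, "p_value": float(pval),
                          "driver": bool(pval < alpha)}

    config = {
        "progenitor_label": progenitor_label, "target": target,
        "other": other, "top_n_de": top_n_de, "seed": seed,
        "alpha": alpha, "null_proportion": null_proportion,
        "n_steps": n_steps, "solver": spec.method,
        "velocity_scale": spec.velocity_scale,
        "baseline_diagnostic": diag,
    }
    return PerturbationReport(baseline_counts, per_gene, de, n,
                              progenitor_label, config)
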