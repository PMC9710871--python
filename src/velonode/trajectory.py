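"""Integrate the learned vector field as an initial value problem.

A trajectory is a sequence of *discrete* recorded states.  Each discrete
step comprises ``intermediate_steps`` solver steps; a solver step is one
forward-Euler update x <- x + dt * s * f(x) with dt = ``step_time``
(default 1), or the equivalent span of an adaptive Runge-Kutta solver
(RK23 / DOP853 from scipy).  The velocity scaling factor ``s`` (default
0.65) calibrates velocity units against the unit integration time step.

Drift correction ("dead reckoning" mitigation): at the end of each discrete
step the current state can be *anchored* — projected onto the top principal
components of a reference dataset, its K nearest reference cells found, and
the state replaced by their mean expression profile — so simulated states
adhere to the data manifold.  Retrograde integration negates the right-hand
side to reconstruct the path that would have produced a terminal state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from sklearn.decomposition import PCA

from .data import Dataset

__all__ = [
    "IntegratorSpec",
    "Trajectory",
    "StepBudget",
    "GeneClamp",
    "ReferenceProjection",
    "fit_reference_projection",
    "estimate_step_budget",
    "integrate",
    "integrate_retrograde",
    "integrate_batch",
]


@dataclass
class IntegratorSpec:
    """How to integrate: solver, scaling, anchoring, and step layout."""

    method: str = "euler"            # euler | rk23 | dop853
    velocity_scale: float = 0.65
    n_steps: int = 15                # discrete (recorded) steps
    intermediate_steps: int = 5      # Euler substeps per discrete step
    anchor: bool = False
    anchor_k: int = 5
    pca_dims: int = 30
    clip_nonnegative: bool = True
    step_time: float = 1.0           # solver time per intermediate step
    rtol: float = 1e-3
    atol: float = 1e-6

    def __post_init__(self) -> None:
        if self.method not in ("euler", "rk23", "dop853"):
            raise ValueError(f"unknown solver {self.method!r}")
        if not (0 < self.velocity_scale <= 2):
            raise ValueError("velocity_scale must be in (0, 2]")
        if self.n_steps < 1 or self.intermediate_steps < 1 or self.anchor_k < 1:
            raise ValueError("n_steps, intermediate_steps, anchor_k must be >= 1")


@dataclass
class Trajectory:
    """Ordered (time, state) sequence with integration provenance."""

    states: np.ndarray               # (n_recorded+1, n_genes)
    times: np.ndarray
    direction: str                   # forward | retrograde
    anchor_events: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    spec: IntegratorSpec | None = None
    diagnostic: str | None = None


@dataclass
class StepBudget:
    """Per-gene step tolerances and the resulting maximum step count."""

    max_steps: int
    per_gene_step_counts: np.ndarray
    percentile_used: float
    excluded_genes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GeneClamp:
    """Hold one gene at a fixed value; re-applied after every integration
    substep and anchoring event (an in-silico sustained activation)."""

    gene_index: int
    value: float

    def apply(self, X: np.ndarray) -> np.ndarray:
        X[..., self.gene_index] = self.value
        return X


class ReferenceProjection:
    """Deterministic PCA projection of a reference dataset, with exact
    nearest-neighbor lookup (ties broken by lowest cell index)."""

    def __init__(self, pca: PCA, reference_expression: np.ndarray):
        self.pca = pca
        self.reference_expression = reference_expression
        self.reference_coords = pca.transform(reference_expression)

    @property
    def n_components(self) -> int:
        return self.pca.n_components_

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(np.atleast_2d(X))

    def nearest(self, X: np.ndarray, k: int) -> np.ndarray:
        """Indices of the k nearest reference cells for each row of X,
        in PCA space; stable sort keeps equidistant ties index-ordered."""
        Q = self.transform(X)
        R = self.reference_coords
        d2 = (Q**2).sum(1)[:, None] - 2 * Q @ R.T + (R**2).sum(1)[None, :]
        return np.argsort(d2, axis=1, kind="stable")[:, :k]

    def anchor_states(self, X: np.ndarray, k: int):
        """Mean expression profile of the k nearest reference cells."""
        nn = self.nearest(X, k)
        anchored = self.reference_expression[nn].mean(axis=1)
        return anchored, nn


def fit_reference_projection(ds: Dataset, pca_dims: int = 30) -> ReferenceProjection:
    """Fit the top-``pca_dims`` PC basis of the reference expression matrix
    (full deterministic SVD).  Rank-deficient data reduce the dimension with
    a warning."""
    if ds.n_cells <= pca_dims:
        raise ValueError(
            f"n_cells={ds.n_cells} must exceed pca_dims={pca_dims}"
        )
    X = ds.expression
    max_rank = min(X.shape[0] - 1, X.shape[1])
    dims = min(pca_dims, max_rank)
    if dims < pca_dims:
        warnings.warn(
            f"requested {pca_dims} PCs but data support {dims}; reduced",
            stacklevel=2,
        )
    pca = PCA(n_components=dims, svd_solver="full")
    pca.fit(X)
    return ReferenceProjection(pca, X)


def estimate_step_budget(ds: Dataset, percentile: float = 95.0) -> StepBudget:
    """Maximum number of integration steps to reach a terminal state.

    For each gene the tolerated step count is its ±2 SD expression range
    (width 4·SD) divided by the gene's mean absolute velocity; the budget is
    the given percentile (95–99) of these counts, i.e. enough steps for a
    2 SD change in expression of at least that fraction of genes.  Genes with
    zero mean |velocity| are excluded.
    """
    if not (95.0 <= percentile <= 99.0):
        raise ValueError("percentile must be in [95, 99]")
    sd = ds.expression.std(axis=0)
    mean_abs_v = np.abs(ds.velocity).mean(axis=0)
    keep = mean_abs_v > 0
    if not keep.any():
        raise ValueError("all genes have zero mean |velocity|")
    excluded = [g for g, k in zip(ds.gene_names, keep) if not k]
    counts = 4.0 * sd[keep] / mean_abs_v[keep]
    max_steps = max(1, math.ceil(np.percentile(counts, percentile)))
    return StepBudget(max_steps, counts, percentile, excluded)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _advance_discrete(field, X: np.ndarray, spec: IntegratorSpec, sign: float,
                      clamp: GeneClamp | None) -> np.ndarray:
    """One discrete step (= ``intermediate_steps`` solver steps) for a batch
    of states."""
    s = spec.velocity_scale
    if spec.method == "euler":
        dt = spec.step_time
        for _ in range(spec.intermediate_steps):
            X = X + dt * sign * s * field.predict(X)
            if clamp is not None:
                X = clamp.apply(X)
        return X
    method = {"rk23": "RK23", "dop853": "DOP853"}[spec.method]
    horizon = spec.step_time * spec.intermediate_steps
    out = np.empty_like(X)
    for i, x in enumerate(X):
        def rhs(_t, y):
            v = sign * s * field.predict(y[None, :])[0]
            return v
        sol = solve_ivp(rhs, (0.0, horizon), x, method=method,
                        rtol=spec.rtol, atol=spec.atol)
        out[i] = sol.y[:, -1]
    if clamp is not None:
        out = clamp.apply(out)
    return out


def integrate_batch(field, X0: np.ndarray, spec: IntegratorSpec,
                    reference: Dataset | ReferenceProjection | None = None,
                    clamp: GeneClamp | None = None,
                    direction: str = "forward"):
    """Integrate many initial states at once.

    Returns ``(states, times, anchor_events, diagnostic)`` where ``states``
    has shape ``(n_steps+1, n_cells, n_genes)``.  Used by the criticality,
    cell-fate and coexpression pipelines where per-cell Python loops would
    dominate the runtime.
    """
    if direction not in ("forward", "retrograde"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "forward" else -1.0
    proj: ReferenceProjection | None = None
    if spec.anchor:
        if reference is None:
            raise ValueError("anchoring requested but no reference provided")
        proj = (reference if isinstance(reference, ReferenceProjection)
                else fit_reference_projection(reference, spec.pca_dims))

    X = np.atleast_2d(np.asarray(X0, dtype=float)).copy()
    recorded = [X.copy()]
    times = [0.0]
    anchor_events: list[tuple[int, tuple[int, ...]]] = []
    diagnostic = None
    for step in range(1, spec.n_steps + 1):
        X = _advance_discrete(field, X, spec, sign, clamp)
        if not np.isfinite(X).all():
            diagnostic = (
                f"non-finite state at discrete step {step}; "
                "returning partial trajectory"
            )
            break
        if spec.clip_nonnegative:
            X = np.maximum(X, 0.0)
            if clamp is not None:
                X = clamp.apply(X)
        if proj is not None:
            X, nn = proj.anchor_states(X, spec.anchor_k)
            if clamp is not None:
                X = clamp.apply(X)
            anchor_events.append((step, tuple(map(int, nn[0]))))
        recorded.append(X.copy())
        times.append(sign * step * spec.step_time * spec.intermediate_steps)
    return np.array(recorded), np.array(times), anchor_events, diagnostic


def integrate(field, x0: np.ndarray, spec: IntegratorSpec,
              reference: Dataset | ReferenceProjection | None = None,
              clamp: GeneClamp | None = None) -> Trajectory:
    """Forward trajectory from a single initial state ``x0``."""
    x0 = np.asarray(x0, dtype=float)
    if not np.isfinite(x0).all():
        raise ValueError("x0 must be finite")
    states, times, events, diag = integrate_batch(
        field, x0[None, :], spec, reference, clamp, "forward"
    )
    return Trajectory(states[:, 0, :], times, "forward", events, spec, diag)


def integrate_retrograde(field, x0: np.ndarray, spec: IntegratorSpec,
                         reference: Dataset | ReferenceProjection | None = None,
                         clamp: GeneClamp | None = None) -> Trajectory:
    """Retrograde trajectory (negated right-hand side): x_{t-1} = x_t - f(x_t)."""
    x0 = np.asarray(x0, dtype=float)
    if not np.isfinite(x0).all():
        raise ValueError("x0 must be finite")
    states, times, events, diag = integrate_batch(
        field, x0[None, :], spec, reference, clamp, "retrograde"
    )
    return Trajectory(states[:, 0, :], times, "retrograde", events, spec, diag)
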