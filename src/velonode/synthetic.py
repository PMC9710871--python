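"""Ground-truth bistable dynamical systems with scRNA-seq-like noise.

The canonical testbed is a two-gene toggle switch — mutually repressing
genes with Hill kinetics:

    dx1/dt = a / (1 + x2^h) - x1
    dx2/dt = a / (1 + x1^h) - x2        (defaults a=2, h=4)

which has two stable attractors (x1-high and x2-high) separated by a saddle
on the diagonal (exactly (1,1) for a=2, h=4, since x^5 + x - 2 = 0 there).
Bystander genes ride on top of the core: *responder* genes relax toward a
weighted copy of one core gene (so they co-vary with it along trajectories —
a planted coexpression module and realistic fate-correlated passengers),
and *null* genes relax toward a private constant, carrying no fate
information whatsoever (negative controls for the driver screen).

Sampling emulates a velocity-annotated scRNA-seq experiment: initial states
scattered across the basin boundary are integrated for random times to
populate the manifold; the true velocity is recorded at each sampled state;
then multiplicative log-normal count noise and Bernoulli dropout corrupt the
*observed* expression.  Every cell's true terminal fate (from noiseless
high-accuracy integration) and its distance to the saddle travel along in
``obs_meta``, so downstream modules can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .data import Dataset

__all__ = ["SyntheticSystem", "make_toggle_switch", "sample_cells",
           "true_terminal"]

PROGENITOR_LABEL = "Progenitor"
FATE_A = "FateA"   # x1-high attractor
FATE_B = "FateB"   # x2-high attractor
UNDETERMINED = "undetermined"


@dataclass
class SyntheticSystem:
    """A known vector field plus the bookkeeping needed for oracles."""

    a: float
    h: float
    n_bystander_genes: int
    resp_a_idx: np.ndarray        # responders tracking core gene 1
    resp_b_idx: np.ndarray        # responders tracking core gene 2
    null_idx: np.ndarray          # fate-uninformative genes
    resp_weights_a: np.ndarray
    resp_weights_b: np.ndarray
    null_levels: np.ndarray
    attractors: list[np.ndarray]  # full-dimension fixed points [A, B]
    saddle_points: list[np.ndarray]
    gene_names: list[str]
    dropout_rate: float = 0.05
    count_noise_scale: float = 0.15
    seed: int = 0
    driver_genes: tuple[int, int] = (0, 1)
    progenitor_band: float = 0.5

    @property
    def n_genes(self) -> int:
        return 2 + self.n_bystander_genes

    @property
    def module_a_genes(self) -> list[str]:
        """The planted coexpression module: core gene 1 and its responders."""
        return [self.gene_names[0]] + [self.gene_names[i]
                                       for i in self.resp_a_idx]

    def rhs(self, X: np.ndarray) -> np.ndarray:
        """True vector field; accepts a state vector or a batch of states."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        x1, x2 = X[:, 0], X[:, 1]
        out = np.empty_like(X)
        out[:, 0] = self.a / (1.0 + x2**self.h) - x1
        out[:, 1] = self.a / (1.0 + x1**self.h) - x2
        if len(self.resp_a_idx):
            out[:, self.resp_a_idx] = (self.resp_weights_a[None, :]
                                       * x1[:, None]) - X[:, self.resp_a_idx]
        if len(self.resp_b_idx):
            out[:, self.resp_b_idx] = (self.resp_weights_b[None, :]
                                       * x2[:, None]) - X[:, self.resp_b_idx]
        if len(self.null_idx):
            out[:, self.null_idx] = self.null_levels[None, :] \
                - X[:, self.null_idx]
        return out[0] if single else out

    def core_rhs(self, x: np.ndarray) -> np.ndarray:
        x1, x2 = x
        return np.array([self.a / (1.0 + x2**self.h) - x1,
                         self.a / (1.0 + x1**self.h) - x2])

    def steady_bystanders(self, core: np.ndarray) -> np.ndarray:
        """Bystander fixed point given a fixed core state."""
        y = np.zeros(self.n_bystander_genes)
        full = np.zeros(self.n_genes)
        full[:2] = core
        if len(self.resp_a_idx):
            full[self.resp_a_idx] = self.resp_weights_a * core[0]
        if len(self.resp_b_idx):
            full[self.resp_b_idx] = self.resp_weights_b * core[1]
        if len(self.null_idx):
            full[self.null_idx] = self.null_levels
        return full


def make_toggle_switch(n_bystander_genes: int = 18, seed: int = 0,
                       a: float = 2.0, h: float = 4.0,
                       dropout_rate: float = 0.05,
                       count_noise_scale: float = 0.15,
                       progenitor_band: float = 0.5) -> SyntheticSystem:
    """Build the bistable toggle-switch system with bystander genes.

    Bystanders are split (in thirds, rounding down for the null group) into
    responders of core gene 1, responders of core gene 2, and null genes.
    """
    if n_bystander_genes < 0:
        raise ValueError("n_bystander_genes must be >= 0")
    rng = np.random.default_rng(seed)
    n_resp_a = (n_bystander_genes + 2) // 3
    n_resp_b = (n_bystander_genes + 1) // 3
    n_null = n_bystander_genes - n_resp_a - n_resp_b
    idx = np.arange(2, 2 + n_bystander_genes)
    resp_a_idx = idx[:n_resp_a]
    resp_b_idx = idx[n_resp_a:n_resp_a + n_resp_b]
    null_idx = idx[n_resp_a + n_resp_b:]
    resp_weights_a = rng.uniform(0.8, 1.2, n_resp_a)
    resp_weights_b = rng.uniform(0.8, 1.2, n_resp_b)
    null_levels = rng.uniform(0.5, 1.5, n_null)
    gene_names = (["core_a", "core_b"]
                  + [f"resp_a_{i}" for i in range(n_resp_a)]
                  + [f"resp_b_{i}" for i in range(n_resp_b)]
                  + [f"null_{i}" for i in range(n_null)])

    sys = SyntheticSystem(
        a=a, h=h, n_bystander_genes=n_bystander_genes,
        resp_a_idx=resp_a_idx, resp_b_idx=resp_b_idx, null_idx=null_idx,
        resp_weights_a=resp_weights_a, resp_weights_b=resp_weights_b,
        null_levels=null_levels, attractors=[], saddle_points=[],
        gene_names=gene_names, dropout_rate=dropout_rate,
        count_noise_scale=count_noise_scale, seed=seed,
        progenitor_band=progenitor_band,
    )
    core_a = fsolve(sys.core_rhs, np.array([a, 0.05]), full_output=False,
                    xtol=1e-13)
    core_b = fsolve(sys.core_rhs, np.array([0.05, a]), full_output=False,
                    xtol=1e-13)
    core_s = fsolve(sys.core_rhs, np.array([1.0, 1.0]), xtol=1e-13)
    sys.attractors = [sys.steady_bystanders(core_a),
                      sys.steady_bystanders(core_b)]
    sys.saddle_points = [sys.steady_bystanders(core_s)]
    for fp in sys.attractors + sys.saddle_points:
        resid = np.linalg.norm(sys.rhs(fp))
        if resid >= 1e-6:
            raise RuntimeError(f"fixed point residual {resid:.2e} too large")
    return sys


def _rk4_batch(sys: SyntheticSystem, X: np.ndarray, t: np.ndarray,
               dt: float) -> np.ndarray:
    """Fixed-step RK4 of the true field for a batch, each row integrated for
    its own duration (rounded to a multiple of dt)."""
    X = X.copy()
    steps = np.round(t / dt).astype(int)
    for k in range(steps.max()):
        active = steps > k
        if not active.any():
            break
        x = X[active]
        k1 = sys.rhs(x)
        k2 = sys.rhs(x + 0.5 * dt * k1)
        k3 = sys.rhs(x + 0.5 * dt * k2)
        k4 = sys.rhs(x + dt * k3)
        X[active] = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return X


def _fate_from_core(sys: SyntheticSystem, core: np.ndarray,
                    radius: float = 0.2) -> np.ndarray:
    """Vectorized fate labels from (already converged) core states."""
    labels = np.full(len(core), UNDETERMINED, dtype=object)
    for att, lab in zip(sys.attractors, (FATE_A, FATE_B)):
        d = np.linalg.norm(core - att[:2], axis=1)
        labels[d < radius] = lab
    return labels


def sample_cells(sys: SyntheticSystem, n_cells: int, seed: int = 0,
                 dropout_rate: float | None = None,
                 count_noise_scale: float | None = None,
                 noise_on_velocity: bool = False,
                 t_max: float = 8.0) -> Dataset:
    """Draw a velocity-annotated dataset from the true dynamics.

    Returns a :class:`Dataset` whose ``obs_meta`` carries ``true_fate`` (from
    noiseless integration of each cell's clean state), ``true_time``, and
    ``dist_saddle`` (core-space distance to the saddle).  Cells within the
    progenitor band around the saddle are labeled ``Progenitor``; the rest
    carry their true fate label.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    dropout = sys.dropout_rate if dropout_rate is None else dropout_rate
    sigma = (sys.count_noise_scale if count_noise_scale is None
             else count_noise_scale)
    rng = np.random.default_rng(seed)

    X0 = np.empty((n_cells, sys.n_genes))
    X0[:, :2] = rng.uniform(0.05, 2.2, (n_cells, 2))
    if sys.n_bystander_genes:
        X0[:, 2:] = rng.uniform(0.0, 2.0, (n_cells, sys.n_bystander_genes))
    t = rng.uniform(0.0, t_max, n_cells)
    clean = _rk4_batch(sys, X0, t, dt=0.02)
    velocity = sys.rhs(clean)

    # ground truth: converge each clean state, then read off the attractor
    converged = _rk4_batch(sys, clean, np.full(n_cells, 40.0), dt=0.05)
    true_fate = _fate_from_core(sys, converged[:, :2])
    dist_saddle = np.linalg.norm(clean[:, :2] - sys.saddle_points[0][:2],
                                 axis=1)
    labels = np.where(dist_saddle < sys.progenitor_band,
                      PROGENITOR_LABEL, true_fate)

    expression = clean * np.exp(rng.normal(0.0, sigma, clean.shape)) \
        if sigma > 0 else clean.copy()
    if dropout > 0:
        expression[rng.random(expression.shape) < dropout] = 0.0
    vel_obs = velocity
    if noise_on_velocity and sigma > 0:
        vel_obs = velocity * np.exp(rng.normal(0.0, sigma, velocity.shape))

    meta = pd.DataFrame({
        "true_fate": true_fate,
        "true_time": t,
        "dist_saddle": dist_saddle,
    })
    return Dataset(np.maximum(expression, 0.0), vel_obs,
                   list(sys.gene_names), [str(v) for v in labels], meta)


def true_terminal(sys: SyntheticSystem, x0: np.ndarray,
                  t_end: float = 60.0, radius: float = 0.2) -> str:
    """High-accuracy fate oracle: integrate the true field from ``x0`` and
    name the attractor reached (or ``"undetermined"``)."""
    x0 = np.asarray(x0, dtype=float)
    sol = solve_ivp(lambda _t, y: sys.rhs(y), (0.0, t_end), x0,
                    method="DOP853", rtol=1e-10, atol=1e-12)
    final_core = sol.y[:2, -1]
    for att, lab in zip(sys.attractors, (FATE_A, FATE_B)):
        if np.linalg.norm(final_core - att[:2]) < radius:
            return lab
    return UNDETERMINED
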