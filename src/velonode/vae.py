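"""Learn the vector field f: expression state -> RNA velocity.

The field is a denoising variational autoencoder: a two-layer encoder maps the
expression state to the location and log-scale of a diagonal Gaussian over a
low-dimensional latent code, and a two-layer decoder maps a latent sample to
the predicted velocity.  The information bottleneck restricts simulated cell
transitions to movements along the low-dimensional manifold the data occupy.

Training minimizes

    MSE(v, v_hat) + kl_weight * KL(q(z|x) || N(0, I)) + l1 * sum_l mean|a_l|

with the Adam optimizer, the reparameterization trick for the latent sample,
and early stopping on a held-out validation split.  Optionally a small
exponentially distributed noise is added to the *inputs* during training
(denoising mode), which regularizes extrapolation to out-of-sample states.

The network is small (defaults: hidden 64, latent 16) and is implemented in
plain numpy with hand-derived gradients; at these sizes a framework buys
nothing and the dependency footprint stays minimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import Dataset

__all__ = [
    "VAEArchitecture",
    "TrainConfig",
    "VelocityField",
    "AnalyticField",
    "train_field",
    "predict_velocity",
    "encode",
    "fit_linear_baseline",
]

_PARAM_NAMES = ("W1", "b1", "Wm", "bm", "Wv", "bv", "W4", "b4", "W5", "b5")


@dataclass
class VAEArchitecture:
    """Network shape. ``input_dim`` is the number of (velocity) genes."""

    input_dim: int
    hidden_dim: int = 64
    latent_dim: int = 16
    l1_lambda: float = 1e-6
    kl_weight: float = 1e-3

    def __post_init__(self) -> None:
        import warnings

        if not (self.latent_dim < self.hidden_dim):
            warnings.warn(
                "degenerate bottleneck: latent_dim >= hidden_dim", stacklevel=2
            )
        if not (self.hidden_dim < self.input_dim):
            warnings.warn(
                "hidden_dim >= input_dim: the autoencoder is not compressing",
                stacklevel=2,
            )


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 1000
    early_stop_patience: int = 3
    denoise_noise_rate: float | None = None  # ×(per-gene SD); None disables
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if not (0 < self.validation_fraction <= 0.5):
            raise ValueError("validation_fraction must be in (0, 0.5]")


class VelocityField:
    """A trained vector field, callable as state -> velocity.

    With ``sample=False`` (the default) prediction routes the latent mean
    through the decoder and is fully deterministic, which is what ODE
    integration requires; ``sample=True`` draws z ~ N(mu, diag(sigma^2)).
    """

    def __init__(self, arch: VAEArchitecture, params: dict[str, np.ndarray],
                 history: dict[str, list[float]], seed: int):
        self.arch = arch
        self.params = params
        self.history = history
        self.seed = seed

    # -- forward passes -----------------------------------------------------

    def _encode(self, X: np.ndarray):
        p = self.params
        h1 = np.maximum(X @ p["W1"] + p["b1"], 0.0)
        mu = h1 @ p["Wm"] + p["bm"]
        logvar = h1 @ p["Wv"] + p["bv"]
        return h1, mu, logvar

    def _decode(self, Z: np.ndarray):
        p = self.params
        h2 = np.maximum(Z @ p["W4"] + p["b4"], 0.0)
        return h2, h2 @ p["W5"] + p["b5"]

    def predict(self, states: np.ndarray, sample: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        if states.shape[1] != self.arch.input_dim:
            raise ValueError(
                f"expected {self.arch.input_dim} genes, got {states.shape[1]}"
            )
        if states.shape[0] == 0:
            return np.empty((0, self.arch.input_dim))
        if not np.isfinite(states).all():
            raise ValueError("states must be finite")
        _, mu, logvar = self._encode(states)
        if sample:
            rng = np.random.default_rng(self.seed) if rng is None else rng
            z = mu + rng.standard_normal(mu.shape) * np.exp(0.5 * logvar)
        else:
            z = mu
        _, out = self._decode(z)
        return out

    __call__ = predict

    def encode(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        if states.shape[1] != self.arch.input_dim:
            raise ValueError(
                f"expected {self.arch.input_dim} genes, got {states.shape[1]}"
            )
        return self._encode(states)[1]

    # -- loss bookkeeping ---------------------------------------------------

    def loss_components(self, X: np.ndarray, V: np.ndarray) -> dict[str, float]:
        """Deterministic (z = mu) loss decomposition on one batch; every term
        is non-negative and the total is their sum."""
        h1, mu, logvar = self._encode(X)
        h2, out = self._decode(mu)
        recon = float(np.mean((out - V) ** 2))
        kl = self.arch.kl_weight * float(
            np.mean(0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar))
        )
        l1 = self.arch.l1_lambda * float(
            np.mean(np.abs(h1)) + np.mean(np.abs(mu))
            + np.mean(np.abs(h2)) + np.mean(np.abs(out))
        )
        return {"recon": recon, "kl": kl, "l1": l1,
                "total": recon + kl + l1}

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str) -> None:
        payload = {
            "arch": asdict(self.arch),
            "seed": self.seed,
            "history": self.history,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "VelocityField":
        with open(path) as fh:
            payload = json.load(fh)
        arch = VAEArchitecture(**payload["arch"])
        params = {k: np.array(v, dtype=float)
                  for k, v in payload["params"].items()}
        return cls(arch, params, payload["history"], payload["seed"])


class AnalyticField:
    """Wrap an analytic vector field ``f(x)`` behind the VelocityField
    prediction contract (used for solver verification and by the synthetic
    ground-truth systems)."""

    def __init__(self, fn, n_genes: int):
        self.fn = fn
        self.n_genes = n_genes

    def predict(self, states: np.ndarray, sample: bool = False,
                rng=None) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        out = np.apply_along_axis(self.fn, 1, states) if states.size else \
            np.empty((0, self.n_genes))
        return np.asarray(out, dtype=float)

    __call__ = predict


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _init_params(arch: VAEArchitecture, rng: np.random.Generator):
    def glorot(n_in, n_out):
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, size=(n_in, n_out))

    G, H, L = arch.input_dim, arch.hidden_dim, arch.latent_dim
    return {
        "W1": glorot(G, H), "b1": np.zeros(H),
        "Wm": glorot(H, L), "bm": np.zeros(L),
        "Wv": glorot(H, L), "bv": np.zeros(L),
        "W4": glorot(L, H), "b4": np.zeros(H),
        "W5": glorot(H, G), "b5": np.zeros(G),
    }


def _forward_backward(params, arch: VAEArchitecture, X, V, eps):
    """One stochastic forward/backward pass; returns (loss, grads)."""
    B, G = X.shape
    H, L = arch.hidden_dim, arch.latent_dim
    lam, kw = arch.l1_lambda, arch.kl_weight

    a1 = X @ params["W1"] + params["b1"]
    h1 = np.maximum(a1, 0.0)
    mu = h1 @ params["Wm"] + params["bm"]
    logvar = h1 @ params["Wv"] + params["bv"]
    sigma = np.exp(0.5 * logvar)
    z = mu + eps * sigma
    a2 = z @ params["W4"] + params["b4"]
    h2 = np.maximum(a2, 0.0)
    out = h2 @ params["W5"] + params["b5"]

    diff = out - V
    recon = np.mean(diff**2)
    kl = kw * np.mean(0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar))
    l1 = lam * (np.mean(np.abs(h1)) + np.mean(np.abs(z))
                + np.mean(np.abs(h2)) + np.mean(np.abs(out)))
    loss = recon + kl + l1

    g = {}
    d_out = 2.0 * diff / (B * G) + lam * np.sign(out) / (B * G)
    g["W5"] = h2.T @ d_out
    g["b5"] = d_out.sum(axis=0)
    d_h2 = d_out @ params["W5"].T + lam * np.sign(h2) / (B * H)
    d_h2 *= (a2 > 0)
    g["W4"] = z.T @ d_h2
    g["b4"] = d_h2.sum(axis=0)
    d_z = d_h2 @ params["W4"].T + lam * np.sign(z) / (B * L)
    d_mu = d_z + kw * mu / (B * L)
    d_logvar = d_z * eps * 0.5 * sigma \
        + kw * 0.5 * (np.exp(logvar) - 1.0) / (B * L)
    d_h1 = d_mu @ params["Wm"].T + d_logvar @ params["Wv"].T \
        + lam * np.sign(h1) / (B * H)
    g["Wm"] = h1.T @ d_mu
    g["bm"] = d_mu.sum(axis=0)
    g["Wv"] = h1.T @ d_logvar
    g["bv"] = d_logvar.sum(axis=0)
    d_h1 *= (a1 > 0)
    g["W1"] = X.T @ d_h1
    g["b1"] = d_h1.sum(axis=0)
    return loss, g


def train_field(ds: Dataset, arch: VAEArchitecture | None = None,
                cfg: TrainConfig | None = None) -> VelocityField:
    """Fit the denoising VAE vector field on (expression, velocity) pairs.

    Cells are split into train/validation once (seeded); after every epoch the
    deterministic validation loss is recorded and training stops when it has
    not improved for ``early_stop_patience`` consecutive epochs (or at
    ``max_epochs``).  The parameters from the best validation epoch are kept.
    """
    arch = arch or VAEArchitecture(input_dim=ds.n_genes)
    cfg = cfg or TrainConfig()
    if arch.input_dim != ds.n_genes:
        raise ValueError("arch.input_dim must equal ds.n_genes")
    if ds.n_cells < cfg.batch_size:
        raise ValueError(
            f"n_cells={ds.n_cells} < batch_size={cfg.batch_size}"
        )

    rng = np.random.default_rng(cfg.seed)
    n = ds.n_cells
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X_tr, V_tr = ds.expression[train_idx], ds.velocity[train_idx]
    X_val, V_val = ds.expression[val_idx], ds.velocity[val_idx]

    noise_scale = None
    if cfg.denoise_noise_rate is not None:
        gene_sd = X_tr.std(axis=0)
        noise_scale = cfg.denoise_noise_rate * gene_sd

    params = _init_params(arch, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v2 = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps_adam, t = 0.9, 0.999, 1e-8, 0

    field = VelocityField(arch, params, {"train_loss": [], "val_loss": []},
                          cfg.seed)
    best_val, best_params, best_epoch, bad_epochs = np.inf, None, -1, 0

    n_tr = len(train_idx)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        epoch_losses = []
        for start in range(0, n_tr, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            Xb = X_tr[batch]
            if noise_scale is not None:
                Xb = Xb + rng.exponential(1.0, size=Xb.shape) * noise_scale
            eps = rng.standard_normal((len(batch), arch.latent_dim))
            loss, grads = _forward_backward(params, arch, Xb,
                                            V_tr[batch], eps)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "try a lower learning rate"
                )
            epoch_losses.append(loss)
            t += 1
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v2[k] = beta2 * v2[k] + (1 - beta2) * grads[k] ** 2
                m_hat = m[k] / (1 - beta1**t)
                v_hat = v2[k] / (1 - beta2**t)
                params[k] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat)
                                                          + eps_adam)
        val_loss = field.loss_components(X_val, V_val)["total"]
        field.history["train_loss"].append(float(np.mean(epoch_losses)))
        field.history["val_loss"].append(float(val_loss))
        if val_loss < best_val:
            best_val, best_epoch, bad_epochs = val_loss, epoch, 0
            best_params = {k: v.copy() for k, v in params.items()}
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stop_patience:
                break
    if best_params is not None:
        field.params = best_params
    field.history["best_epoch"] = best_epoch
    return field


def predict_velocity(field: VelocityField, states: np.ndarray,
                     sample: bool = False,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Velocity estimates for a batch of states (see
    :meth:`VelocityField.predict`)."""
    return field.predict(states, sample=sample, rng=rng)


def encode(field: VelocityField, states: np.ndarray) -> np.ndarray:
    """Latent means mu(x) — the manifold embedding combining expression and
    velocity information, suitable for 2-D visualization downstream."""
    return field.encode(states)


def fit_linear_baseline(X_train: np.ndarray, V_train: np.ndarray):
    """Ordinary-least-squares velocity predictor (with intercept).

    The simplest competing vector-field model; used as the reference the
    nonlinear field must beat on held-out velocity MSE.
    """
    Xd = np.column_stack([X_train, np.ones(len(X_train))])
    coef, *_ = np.linalg.lstsq(Xd, V_train, rcond=None)

    def predict(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.column_stack([X, np.ones(len(X))]) @ coef

    return predict
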