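"""Per-cell instability scores: the cell criticality index (CCI) and StemID
entropy.

StemID treats a cell's (normalized) expression vector as a probability
distribution and scores its Shannon entropy — a "potential" for
differentiation: pluripotent cells have broad, high-entropy profiles.  The
CCI is instead "kinetic": it simulates T forward steps of the cell under the
learned dynamics and accumulates the KL divergence between the expression
distributions of consecutive states, so cells whose state is about to change
a lot (e.g. near a fate-commitment bifurcation) score high regardless of
their entropy.

Expression vectors are mapped to the simplex with a small pseudocount before
any entropy/KL computation (raw normalized counts neither sum to 1 nor avoid
zeros, and KL is undefined otherwise).  All information quantities are in
nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .trajectory import IntegratorSpec, integrate_batch

__all__ = [
    "CriticalityResult",
    "state_to_distribution",
    "kl_step",
    "stemid_entropy",
    "compute_cci",
    "rank_cci_genes",
]

DEFAULT_PSEUDOCOUNT = 1e-8


@dataclass
class CriticalityResult:
    cci: np.ndarray                  # (n_cells,) possibly NaN where aborted
    stemid: np.ndarray               # (n_cells,)
    per_step_kl: np.ndarray          # (n_cells, T)
    T: int
    spec: IntegratorSpec
    diagnostics: list[str]


def state_to_distribution(x: np.ndarray,
                          pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Map non-negative expression vector(s) to the probability simplex:
    (x + pc) / sum(x + pc).  Works on a vector or a stack of vectors."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("negative expression entries; clip upstream")
    shifted = x + pseudocount
    total = shifted.sum(axis=-1, keepdims=True)
    if (total <= 0).any():
        raise ValueError("state sums to zero even after pseudocount")
    return shifted / total


def kl_step(p_next: np.ndarray, p_curr: np.ndarray) -> float:
    """KL(p_next || p_curr) = sum_i p_next[i] log(p_next[i]/p_curr[i]), nats.

    ``p_curr`` must be strictly positive (guaranteed by the pseudocount);
    zero entries of ``p_next`` contribute 0.
    """
    p_next = np.asarray(p_next, dtype=float)
    p_curr = np.asarray(p_curr, dtype=float)
    if p_next.shape != p_curr.shape:
        raise ValueError("distribution length mismatch")
    if (p_curr <= 0).any():
        raise ValueError("p_curr must be strictly positive")
    mask = p_next > 0
    return float(np.sum(p_next[mask] * np.log(p_next[mask] / p_curr[mask])))


def stemid_entropy(x: np.ndarray,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Shannon entropy -sum p log p of the state's expression distribution."""
    p = state_to_distribution(np.atleast_2d(x), pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1)


def compute_cci(field, ds: Dataset, spec: IntegratorSpec | None = None,
                T: int = 35,
                pseudocount: float = DEFAULT_PSEUDOCOUNT,
                reference: Dataset | None = None) -> CriticalityResult:
    """Cumulative KL divergence over T simulated forward transitions per cell.

    Each cell's observed state is the initial condition; the trajectory uses
    the same anchoring/clipping machinery as the trajectory module (anchored
    integration by default, against ``ds`` itself, so that simulated paths
    reach a steady terminal state on the data manifold).  StemID entropy of
    every initial state is computed alongside.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if spec is None:
        spec = IntegratorSpec(anchor=True, n_steps=T)
    else:
        from dataclasses import replace
        spec = replace(spec, n_steps=T)
    ref = reference if reference is not None else (ds if spec.anchor else None)

    states, _times, _events, diag = integrate_batch(
        field, ds.expression, spec, ref, None, "forward"
    )
    diagnostics = [diag] if diag else []
    n_recorded = states.shape[0] - 1  # may be < T on abort
    n_cells = ds.n_cells
    per_step = np.full((n_cells, T), np.nan)
    dists = state_to_distribution(states, pseudocount)
    for t in range(n_recorded):
        p_curr, p_next = dists[t], dists[t + 1]
        ratio = np.where(p_next > 0, p_next / p_curr, 1.0)
        per_step[:, t] = np.sum(np.where(p_next > 0,
                                         p_next * np.log(ratio), 0.0), axis=1)
    if n_recorded < T:
        diagnostics.append(
            f"only {n_recorded} of {T} transitions recorded; "
            "CCI entries are missing (NaN) beyond the abort point"
        )
        cci = np.full(n_cells, np.nan)
    else:
        cci = per_step.sum(axis=1)
    stemid = stemid_entropy(ds.expression, pseudocount)
    return CriticalityResult(cci, stemid, per_step, T, spec, diagnostics)


def rank_cci_genes(result: CriticalityResult, ds: Dataset) -> pd.DataFrame:
    """Pearson correlation of each gene's expression with the CCI across
    cells, both signs reported, sorted descending.  Zero-variance genes get
    correlation 0 with a flag."""
    if len(result.cci) != ds.n_cells:
        raise ValueError("result is not aligned with ds cells")
    ok = np.isfinite(result.cci)
    cci = result.cci[ok]
    X = ds.expression[ok]
    cci_c = cci - cci.mean()
    denom_c = np.sqrt((cci_c**2).sum())
    Xc = X - X.mean(axis=0)
    gene_ss = np.sqrt((Xc**2).sum(axis=0))
    zero_var = gene_ss == 0
    if denom_c == 0:
        corr = np.zeros(ds.n_genes)
        zero_var = np.ones(ds.n_genes, dtype=bool)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (Xc.T @ cci_c) / (gene_ss * denom_c)
        corr[zero_var] = 0.0
    out = pd.DataFrame({
        "gene": ds.gene_names,
        "correlation": corr,
        "zero_variance": zero_var,
    })
    return out.sort_values("correlation", ascending=False,
                           kind="stable").reset_index(drop=True)
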