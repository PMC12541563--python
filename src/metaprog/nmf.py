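"""Non-negative matrix factorization by Lee-Seung multiplicative updates.

Minimizes the Frobenius reconstruction error ``||X - WH||_F`` for a
non-negative expression matrix X (genes x cells) under entrywise
non-negativity of W (gene loadings) and H (cell activities).  Multiplicative
updates never increase the objective, so the per-iteration objective trace
is monotone non-increasing (up to floating-point round-off).

Initialization is random uniform scaled by ``sqrt(mean(X)/k)`` (so that the
initial product matches X in overall magnitude), seeded for bit-identical
reproducibility.  On return, factors are sorted by decreasing
``||W_j|| * ||H_j||`` and W columns are normalized to unit L2 norm with the
scale folded into H, which makes "top genes per factor" well defined and
comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import NormalizedMatrix
from .errors import ConfigurationError, ContractError

__all__ = ["NMFFactorization", "nmf_factorize"]

_EPS = 1e-10  # entrywise floor protecting the multiplicative denominators


@dataclass
class NMFFactorization:
    """Result of one (possibly multi-restart) factorization."""

    sample_id: str
    k: int
    gene_ids: list[str]
    cell_ids: list[str]
    W: np.ndarray = field(repr=False)   # (genes, k), columns unit L2
    H: np.ndarray = field(repr=False)   # (k, cells)
    objective_trace: list[float] = field(repr=False, default_factory=list)
    seed: int = 0
    n_iter: int = 0
    converged: bool = False

    @property
    def final_error(self) -> float:
        return self.objective_trace[-1]


def _frobenius_error(norm_x2: float, WtX: np.ndarray, W: np.ndarray,
                     H: np.ndarray) -> float:
    # ||X - WH||_F^2 = ||X||^2 - 2<W'X, H> + <W'W, HH'> ; clamp fp negatives
    val = (norm_x2 - 2.0 * float(np.sum(WtX * H))
           + float(np.sum((W.T @ W) * (H @ H.T))))
    return float(np.sqrt(max(val, 0.0)))


def _mu_run(X: np.ndarray, k: int, seed: int, max_iter: int, tol: float):
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W = rng.uniform(size=(X.shape[0], k)) * scale
    H = rng.uniform(size=(k, X.shape[1])) * scale

    norm_x2 = float(np.sum(X * X))
    trace: list[float] = []
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        WtX = W.T @ X
        H *= WtX / np.maximum((W.T @ W) @ H, _EPS)
        XHt = X @ H.T
        W *= XHt / np.maximum(W @ (H @ H.T), _EPS)
        err = _frobenius_error(norm_x2, W.T @ X, W, H)
        trace.append(err)
        if len(trace) >= 2:
            prev = trace[-2]
            if prev <= _EPS or (prev - err) / prev < tol:
                converged = True
                break
    return W, H, trace, n_iter, converged


def _order_and_normalize(W: np.ndarray, H: np.ndarray):
    strength = np.linalg.norm(W, axis=0) * np.linalg.norm(H, axis=1)
    order = np.argsort(-strength, kind="stable")
    W, H = W[:, order], H[order, :]
    wn = np.maximum(np.linalg.norm(W, axis=0), _EPS)
    return W / wn[None, :], H * wn[:, None]


def nmf_factorize(
    x: NormalizedMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    restarts: int = 1,
) -> NMFFactorization:
    """Factorize one sample's normalized matrix at rank ``k``.

    Stops when the relative objective decrease over one iteration drops
    below ``tol``, or at ``max_iter``.  With ``restarts > 1``, runs from
    seeds ``seed, seed+1, ...`` and keeps the run with the smallest final
    error (ties to the lowest seed).  Same arguments give bit-identical
    factors.
    """
    X = np.ascontiguousarray(x.values, dtype=np.float64)
    if X.size and X.min() < 0:
        raise ContractError("NMF input must be non-negative")
    if not 1 <= k <= min(X.shape):
        raise ConfigurationError(
            f"k={k} must be in [1, min(genes, cells)={min(X.shape)}]")
    if max_iter < 1:
        raise ConfigurationError("max_iter must be >= 1")
    if tol <= 0:
        raise ConfigurationError("tol must be > 0")
    if restarts < 1:
        raise ConfigurationError("restarts must be >= 1")

    best = None
    for r in range(restarts):
        run = _mu_run(X, k, seed + r, max_iter, tol)
        if best is None or run[2][-1] < best[1][2][-1]:
            best = (seed + r, run)
    best_seed, (W, H, trace, n_iter, converged) = best
    W, H = _order_and_normalize(W, H)
    return NMFFactorization(
        sample_id=x.sample_id, k=k, gene_ids=list(x.gene_ids),
        cell_ids=list(x.cell_ids), W=W, H=H, objective_trace=trace,
        seed=best_seed, n_iter=n_iter, converged=converged,
    )
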