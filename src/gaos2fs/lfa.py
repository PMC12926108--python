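"""Latent-factor completion of sparse feature blocks.

A rank-L factorisation ``R ~ U V^T`` (U: M x L sample factors, V: H x L
feature factors) is trained by stochastic gradient descent on the observed
cells only, minimising per observed cell (m, j)

    1/2 (f_mj - u_m . v_j)^2 + lambda/2 (||u_m||^2 + ||v_j||^2),

i.e. the regulariser is charged once per observed cell, not once per factor
row.  Missing cells are then filled with the inner products ``u_m . v_j``
while observed cells pass through unchanged.

Factors are initialised uniformly on [0, 0.004): small positive values close
to zero, which keeps the first reconstructions near zero without the exact
symmetry of an all-zero start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DivergenceError

try:  # pragma: no cover - exercised indirectly; equality tested vs reference
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "FactorPair",
    "LfaParams",
    "init_factors",
    "block_loss",
    "sgd_update_cell",
    "train",
    "complete_block",
]


@dataclass
class FactorPair:
    """Latent factor matrices U (M x L) and V (H x L)."""

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.ndim != 2 or self.V.ndim != 2 or self.U.shape[1] != self.V.shape[1]:
            raise ValueError("U and V must be 2-D with a common latent dimension")

    @property
    def L(self) -> int:
        return self.U.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Dense rank-L approximation U V^T."""
        return self.U @ self.V.T


@dataclass
class LfaParams:
    """Training hyper-parameters.

    L=5, eta=0.01, lambda=0.05, 500 epochs and a 1e-5 relative-change stop
    are desk-scale defaults that converge on low-rank blocks of a few
    thousand cells; init_scale 0.004 fixes the initialisation support.

    Because the factors start near zero, the first epochs sit on a flat
    "cold start" plateau where the per-epoch loss change is tiny even though
    training has barely begun; the relative-change stop therefore only
    activates after ``min_epochs`` passes.
    """

    L: int = 5
    learning_rate: float = 0.01
    regularization: float = 0.05
    max_epochs: int = 500
    rel_tol: float = 1e-5
    min_epochs: int = 50
    init_scale: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("latent dimension L must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.min_epochs < 0:
            raise ValueError("min_epochs must be >= 0")


def init_factors(M: int, H: int, L: int, seed: int, init_scale: float = 0.004) -> FactorPair:
    """Draw every factor entry independently, uniformly on [0, init_scale)."""
    if not 1 <= L <= min(M, H):
        raise ValueError(f"L must satisfy 1 <= L <= min(M, H) = {min(M, H)}; got {L}")
    rng = np.random.default_rng(seed)
    return FactorPair(
        U=rng.uniform(0.0, init_scale, size=(M, L)),
        V=rng.uniform(0.0, init_scale, size=(H, L)),
    )


def block_loss(fp: FactorPair, block, lam: float) -> float:
    """Regularised squared loss over the observed cells of ``block``."""
    if fp.U.shape[0] != block.values.shape[0] or fp.V.shape[0] != block.values.shape[1]:
        raise ValueError("factor shapes do not match the block")
    rows, cols = np.nonzero(block.mask)
    resid = block.values[rows, cols] - np.einsum(
        "ij,ij->i", fp.U[rows], fp.V[cols]
    )
    loss = 0.5 * float(np.sum(resid**2))
    if lam > 0:
        loss += 0.5 * lam * float(
            np.sum(fp.U[rows] ** 2) + np.sum(fp.V[cols] ** 2)
        )
    return loss


def sgd_update_cell(
    u_row: np.ndarray,
    v_row: np.ndarray,
    observed_value: float,
    eta: float,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One SGD step on a single observed cell.

    The residual ``err = f - u.v`` is computed once from the pre-update rows
    and both rows are updated simultaneously from their pre-update values:

        u <- u + eta * (err * v - lam * u)
        v <- v + eta * (err * u - lam * v)
    """
    u = np.asarray(u_row, dtype=float)
    v = np.asarray(v_row, dtype=float)
    err = observed_value - float(u @ v)
    u_new = u + eta * err * v - lam * eta * u
    v_new = v + eta * err * u - lam * eta * v
    return u_new, v_new


def _epoch_reference(U, V, values, rows, cols, order, eta, lam):
    """Pure-NumPy epoch: one sequential pass over observed cells (in place)."""
    for idx in order:
        m, j = rows[idx], cols[idx]
        u, v = U[m], V[j]
        err = values[m, j] - float(u @ v)
        u_new = u + eta * err * v - lam * eta * u
        v_new = v + eta * err * u - lam * eta * v
        U[m] = u_new
        V[j] = v_new


if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _epoch_jit(U, V, values, rows, cols, order, eta, lam):  # pragma: no cover
        L = U.shape[1]
        for t in range(order.shape[0]):
            idx = order[t]
            m = rows[idx]
            j = cols[idx]
            err = values[m, j]
            for k in range(L):
                err -= U[m, k] * V[j, k]
            for k in range(L):
                u = U[m, k]
                v = V[j, k]
                U[m, k] = u + eta * err * v - lam * eta * u
                V[j, k] = v + eta * err * u - lam * eta * v

    _epoch = _epoch_jit
else:  # pragma: no cover
    _epoch = _epoch_reference


def train(block, params: LfaParams | None = None, _use_reference: bool = False):
    """Fit factors to a sparse block by SGD over the observed cells.

    Each epoch visits every observed cell exactly once in a seed-controlled
    shuffled order.  Training stops at ``max_epochs`` or when the relative
    loss change between consecutive epochs falls below ``rel_tol``.

    Returns ``(FactorPair, loss_per_epoch)`` where the loss trajectory starts
    with the pre-training loss.
    """
    if params is None:
        params = LfaParams()
    if block.n_observed < 1:
        raise ValueError("cannot train on a block with no observed cells")
    M, H = block.values.shape
    fp = init_factors(M, H, params.L, params.seed, params.init_scale)
    rows, cols = np.nonzero(block.mask)
    rows = rows.astype(np.int64)
    cols = cols.astype(np.int64)
    values = np.ascontiguousarray(block.values)
    values = np.where(block.mask, values, 0.0)  # masked cells never visited
    rng = np.random.default_rng(params.seed)
    eta, lam = params.learning_rate, params.regularization

    epoch_fn = _epoch_reference if _use_reference else _epoch
    losses = [block_loss(fp, block, lam)]
    for epoch in range(1, params.max_epochs + 1):
        order = rng.permutation(rows.shape[0]).astype(np.int64)
        epoch_fn(fp.U, fp.V, values, rows, cols, order, eta, lam)
        loss = block_loss(fp, block, lam)
        if not np.isfinite(loss):
            raise DivergenceError(
                f"SGD diverged (non-finite loss); reduce learning_rate={eta}"
            )
        losses.append(loss)
        prev = losses[-2]
        if (
            epoch >= params.min_epochs
            and prev > 0
            and abs(prev - loss) / prev < params.rel_tol
        ):
            break
    return fp, np.asarray(losses)


def complete_block(block, fp: FactorPair) -> np.ndarray:
    """Dense completion: observed cells pass through, missing cells get u.v."""
    if fp.U.shape[0] != block.values.shape[0] or fp.V.shape[0] != block.values.shape[1]:
        raise ValueError("factor shapes do not match the block")
    recon = fp.reconstruct()
    return np.where(block.mask, block.values, recon)
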