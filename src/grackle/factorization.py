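"""NMF family solvers: plain NMF, GNMF, pr-GNMF and GRACKLE.

All four models minimize

    || Y - W H ||_F^2  +  lambda1 * tr(W^T L_S W)  +  lambda2 * tr(H L_G H^T)

for a nonnegative expression matrix ``Y`` (m samples x n genes), factors
``W`` (m x k) and ``H`` (k x n), and graph Laplacians ``L_S = D_S - S_S``
(sample side) and ``L_G = D_G - S_G`` (gene side).  Setting
``lambda1 = lambda2 = 0`` recovers classical NMF; ``lambda1 = 0`` with a
learned kNN gene graph is GNMF; ``lambda1 = 0`` with a prior GRN-derived
gene graph is pr-GNMF; both penalties active is GRACKLE.

The solver is the classical multiplicative-update scheme extended with
the graph terms:

    W <- W * (Y H^T + lambda1 * S_S W) / (W H H^T + lambda1 * D_S W)
    H <- H * (W^T Y + lambda2 * H S_G) / (W^T W H + lambda2 * H D_G)

Each update is derived from the same auxiliary-function argument as the
single-graph GNMF updates, so the objective is non-increasing at every
iteration; nonnegativity is preserved by construction.  Iteration stops
when the relative Frobenius change in H drops below ``tol`` (default
1e-4) or after ``max_iter`` iterations (default 100).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .graphs import SimilarityGraph

logger = logging.getLogger("grackle")

#: additive denominator stabilizer; prevents 0/0 without altering updates
EPS_DENOM = 1e-12
#: lower bound of the uniform initialization interval (eps, 1]
EPS_INIT = 1e-6

DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-4
#: GNMF settings: 5 nearest neighbors, lambda grid {1, 10, 1e2, 1e3, 1e4}
GNMF_N_NEIGHBORS = 5
GNMF_LAMBDA_GRID = (1.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass
class FactorModel:
    """A fitted factorization ``Y ~ W H`` with its penalty settings."""

    W: np.ndarray
    H: np.ndarray
    k: int
    lambda1: float
    lambda2: float
    loss_history: list[float]
    n_iter: int
    converged: bool
    seed: int

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1] if self.loss_history else np.nan


@dataclass
class ProjectionResult:
    """Held-out samples embedded into the latent space by NNLS."""

    W_test: np.ndarray
    residuals: np.ndarray


def initialize_factors(
    m: int, n: int, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform-random strictly positive factors on (eps, 1]."""
    if k <= 0:
        raise ValueError(f"rank k must be >= 1, got {k}")
    if k > min(m, n):
        warnings.warn(
            f"rank k={k} exceeds min(m, n)={min(m, n)}; factorization is "
            "over-complete", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    W = EPS_INIT + (1.0 - EPS_INIT) * rng.random((m, k))
    H = EPS_INIT + (1.0 - EPS_INIT) * rng.random((k, n))
    return W, H


def _as_matrix(S) -> np.ndarray | None:
    if S is None:
        return None
    return S.matrix if isinstance(S, SimilarityGraph) else np.asarray(S, dtype=float)


def objective(
    Y: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    LS: np.ndarray | None = None,
    LG: np.ndarray | None = None,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
) -> float:
    """Regularized squared-Frobenius reconstruction objective."""
    m, n = Y.shape
    if W.shape[0] != m or H.shape[1] != n or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"nonconformable shapes: Y {Y.shape}, W {W.shape}, H {H.shape}"
        )
    R = Y - W @ H
    val = float((R * R).sum())
    if lambda1 != 0.0:
        if LS is None:
            raise ValueError("lambda1 > 0 requires LS")
        if LS.shape != (m, m):
            raise ValueError(f"LS shape {LS.shape} does not match m={m}")
        val += lambda1 * float(np.trace(W.T @ LS @ W))
    if lambda2 != 0.0:
        if LG is None:
            raise ValueError("lambda2 > 0 requires LG")
        if LG.shape != (n, n):
            raise ValueError(f"LG shape {LG.shape} does not match n={n}")
        val += lambda2 * float(np.trace(H @ LG @ H.T))
    return val


def grackle_update_step(
    Y: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    SS: np.ndarray | None = None,
    DS: np.ndarray | None = None,
    SG: np.ndarray | None = None,
    DG: np.ndarray | None = None,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    eps: float = EPS_DENOM,
) -> tuple[np.ndarray, np.ndarray]:
    """One dual-graph-regularized multiplicative update of (W, H).

    W is updated first with H fixed, then H with the new W.  With
    ``lambda1 = lambda2 = 0`` this is the classical NMF multiplicative
    update.  Zero entries stay zero (multiplicative lock); the objective
    is non-increasing.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    num_W = Y @ H.T
    den_W = W @ (H @ H.T)
    if lambda1 != 0.0:
        num_W = num_W + lambda1 * (SS @ W)
        den_W = den_W + lambda1 * (DS @ W)
    W_new = W * num_W / (den_W + eps)

    num_H = W_new.T @ Y
    den_H = (W_new.T @ W_new) @ H
    if lambda2 != 0.0:
        num_H = num_H + lambda2 * (H @ SG)
        den_H = den_H + lambda2 * (H @ DG)
    H_new = H * num_H / (den_H + eps)

    if not (np.isfinite(W_new).all() and np.isfinite(H_new).all()):
        raise FloatingPointError("non-finite entries produced by update step")
    return W_new, H_new


def fit(
    Y: np.ndarray,
    k: int,
    SS: SimilarityGraph | np.ndarray | None = None,
    SG: SimilarityGraph | np.ndarray | None = None,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    eps: float = EPS_DENOM,
) -> FactorModel:
    """Fit GRACKLE (or any of its special cases) by multiplicative updates.

    Stops when ``||H_t - H_{t-1}||_F / ||H_{t-1}||_F < tol`` or after
    ``max_iter`` iterations.  ``lambda1 = lambda2 = 0`` reproduces plain
    NMF on the identical code path; ``lambda1 = 0, lambda2 > 0`` with a
    prior GRN graph is pr-GNMF.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.size == 0 or not Y.any():
        raise ValueError("Y is empty or all zero")
    if Y.min() < 0:
        raise ValueError("Y contains negative values")
    S_s = _as_matrix(SS)
    S_g = _as_matrix(SG)
    if lambda1 > 0 and S_s is None:
        raise ValueError("lambda1 > 0 requires a sample-similarity graph SS")
    if lambda2 > 0 and S_g is None:
        raise ValueError("lambda2 > 0 requires a gene-similarity graph SG")
    m, n = Y.shape
    DS = LS = None
    if lambda1 > 0:
        ds = S_s.sum(axis=1)
        DS = np.diag(ds)
        LS = DS - S_s
    DG = LG = None
    if lambda2 > 0:
        dg = S_g.sum(axis=1)
        DG = np.diag(dg)
        LG = DG - S_g

    W, H = initialize_factors(m, n, k, seed)
    loss_history = [objective(Y, W, H, LS, LG, lambda1, lambda2)]
    converged = False
    n_iter = 0
    for it in range(1, max_iter + 1):
        H_prev = H
        try:
            W, H = grackle_update_step(
                Y, W, H, S_s, DS, S_g, DG, lambda1, lambda2, eps
            )
        except FloatingPointError as exc:
            raise FloatingPointError(f"{exc} at iteration {it}") from exc
        n_iter = it
        loss_history.append(objective(Y, W, H, LS, LG, lambda1, lambda2))
        denom = np.linalg.norm(H_prev)
        rel_change = np.linalg.norm(H - H_prev) / denom if denom > 0 else 0.0
        if rel_change < tol:
            converged = True
            break
    return FactorModel(
        W=W, H=H, k=k, lambda1=lambda1, lambda2=lambda2,
        loss_history=loss_history, n_iter=n_iter, converged=converged, seed=seed,
    )


def nmf_fit(
    Y: np.ndarray,
    k: int,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> FactorModel:
    """Plain NMF baseline: the lambda1 = lambda2 = 0 case of :func:`fit`."""
    return fit(Y, k, lambda1=0.0, lambda2=0.0, max_iter=max_iter, tol=tol, seed=seed)


def gnmf_fit(
    Y: np.ndarray,
    k: int,
    n_neighbors: int = GNMF_N_NEIGHBORS,
    lambda_grid: tuple[float, ...] = GNMF_LAMBDA_GRID,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> dict[float, FactorModel]:
    """GNMF: gene-side regularization by a learned kNN affinity graph.

    Builds a k-nearest-neighbor graph on the gene axis of ``Y`` and fits
    one model per lambda in ``lambda_grid``; model selection is left to
    the caller's evaluation metric.
    """
    from .graphs import knn_affinity

    SG = knn_affinity(Y, n_neighbors=n_neighbors, axis="gene")
    models: dict[float, FactorModel] = {}
    for lam in lambda_grid:
        models[lam] = fit(
            Y, k, SG=SG, lambda1=0.0, lambda2=float(lam),
            max_iter=max_iter, tol=tol, seed=seed,
        )
    return models


def project_samples(Y_test: np.ndarray, H: np.ndarray) -> ProjectionResult:
    """Embed held-out samples via nonnegative least squares against H.

    Solves ``min_{w >= 0} || y - w H ||_2`` independently for each test
    sample (row of ``Y_test``).
    """
    Y_test = np.asarray(Y_test, dtype=float)
    H = np.asarray(H, dtype=float)
    if Y_test.shape[1] != H.shape[1]:
        raise ValueError(
            f"gene mismatch: Y_test has {Y_test.shape[1]} genes, H has {H.shape[1]}"
        )
    A = H.T  # n_genes x k
    W_rows = []
    resid = []
    for y in Y_test:
        w, r = nnls(A, y)
        W_rows.append(w)
        resid.append(r)
    return ProjectionResult(
        W_test=np.asarray(W_rows), residuals=np.asarray(resid)
    )
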