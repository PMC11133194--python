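"""Alternating least squares estimation of the Tucker3-PCovR model.

Each ALS cycle performs four exact conditional minimizations of the
concatenated loss ``||Q - A S'||^2`` (see :mod:`.core`):

1. **W-step** — with the loadings fixed, the object scores are re-estimated
   through their defining parameterization ``A = X W_X``; the minimizing
   weights have the closed form ``W = (X'X)^+ X' Q S (S'S)^+``.  Solving for
   W rather than a free A keeps the scores in the column space of the
   predictors, which is what makes the interpolation identity ``a = x' W``
   exact for training rows.
2. **B-step** — the attribute components are the orthonormal Procrustes
   solution built from ``Y_B (C (x) A) G_B'``.
3. **C-step** — analogous for the source components from ``Y_C (B (x) A) G_C'``.
4. **Regression step** — the core and the predictor loadings are updated by
   multivariate regression on the current scores:
   ``P_X' = (A'A)^+ A'X`` and ``G_A = (A'A)^+ A' Y_A (C (x) B)``.

Every step can only decrease the loss, so the recorded loss history is
non-increasing.  Because the criterion is multimodal, a multi-start scheme is
used: the first start is rational (eigenvector-based), the remaining starts
are random or perturbations of the rational start, and the lowest-loss
solution wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    CoupledDataset,
    Ranks,
    Tucker3PCovRFit,
    beta_from_alpha,
    build_concatenation,
    loss as eq_loss,
    unfold,
    unfold_core,
)

__all__ = [
    "FitConfig",
    "AlsState",
    "init_rational",
    "init_random",
    "init_perturbed",
    "als_step",
    "fit",
]


@dataclass(frozen=True)
class FitConfig:
    """Settings for one Tucker3-PCovR fit.

    alpha
        Weight of predictor reconstruction versus criterion prediction,
        in [0, 1] (0 = reduced rank regression, 1 = principal component
        regression).
    ranks
        Tucker3 complexity (R1, R2, R3).
    init
        Initialization of starts after the first (always rational):
        ``"perturbed"`` (rational plus Gaussian noise), ``"random"``, or
        ``"rational"`` (extra starts fall back to perturbed).
    n_starts, perturb_scale, tol, max_iter, seed
        Multi-start count, perturbation standard deviation, relative
        loss-decrease convergence threshold, iteration cap, master seed.
    """

    alpha: float
    ranks: Ranks
    init: str = "perturbed"
    n_starts: int = 20
    perturb_scale: float = 0.1
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.init not in ("rational", "random", "perturbed"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.perturb_scale < 0:
            raise ValueError("perturb_scale must be nonnegative")


@dataclass
class AlsState:
    """Current parameter values inside the ALS loop."""

    W: np.ndarray  # L x R1
    A: np.ndarray  # I x R1
    B: np.ndarray  # J x R2, orthonormal columns
    C: np.ndarray  # K x R3, orthonormal columns
    G: np.ndarray  # R1 x R2 x R3
    P_X: np.ndarray  # L x R1


def _fix_eigvec_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-absolute entry of each column positive (determinism)."""
    V = V.copy()
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _leading_eigvecs(M: np.ndarray, r: int, what: str) -> np.ndarray:
    """Top-r orthonormal eigenvectors of a symmetric PSD Gram matrix.

    Pads with an orthonormal complement (and warns) if the matrix rank is
    below r.
    """
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(M.shape) * np.finfo(float).eps * max(vals.max(initial=0.0), 1.0)
    rank = int(np.sum(vals > tol))
    if rank < r:
        warnings.warn(
            f"rational initialization of {what}: requested {r} components but "
            f"the Gram matrix has rank {rank}; padding with an orthonormal "
            "complement",
            stacklevel=3,
        )
    return _fix_eigvec_signs(vecs[:, :r])


def _orthonormalize(M: np.ndarray) -> np.ndarray:
    """QR-based orthonormalization with positive diagonal (idempotent on
    orthonormal input)."""
    Q, R = np.linalg.qr(M)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    return Q * signs


def init_rational(
    X: np.ndarray, Y: np.ndarray, ranks: Ranks
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic eigenvector start.

    B0 and C0 are the leading eigenvectors of the Gram matrices of the
    attribute- and source-mode unfoldings of Y; A0 comes from the Gram matrix
    of the concatenation [X | Y_A], so the initial object components already
    reflect both blocks.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Y_A, Y_B, Y_C = unfold(Y, "A"), unfold(Y, "B"), unfold(Y, "C")
    B0 = _leading_eigvecs(Y_B @ Y_B.T, ranks.R2, "B")
    C0 = _leading_eigvecs(Y_C @ Y_C.T, ranks.R3, "C")
    XY = np.hstack([X, Y_A])
    A0 = _leading_eigvecs(XY @ XY.T, ranks.R1, "A")
    return A0, B0, C0


def init_random(
    dims: tuple[int, int, int], ranks: Ranks, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standard-normal start; B0 and C0 are orthonormalized so the state
    invariants hold from the first iteration."""
    I, J, K = dims
    A0 = rng.standard_normal((I, ranks.R1))
    B0 = _orthonormalize(rng.standard_normal((J, ranks.R2)))
    C0 = _orthonormalize(rng.standard_normal((K, ranks.R3)))
    return A0, B0, C0


def init_perturbed(
    rational: tuple[np.ndarray, np.ndarray, np.ndarray],
    perturb_scale: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rational start plus N(0, perturb_scale^2) noise; scale 0 reproduces the
    rational start exactly."""
    A0, B0, C0 = rational
    if perturb_scale == 0:
        return A0.copy(), B0.copy(), C0.copy()
    A1 = A0 + perturb_scale * rng.standard_normal(A0.shape)
    B1 = _orthonormalize(B0 + perturb_scale * rng.standard_normal(B0.shape))
    C1 = _orthonormalize(C0 + perturb_scale * rng.standard_normal(C0.shape))
    return A1, B1, C1


def _pinv_solve(M: np.ndarray, rhs: np.ndarray, what: str, warn: bool = True) -> np.ndarray:
    """Solve M x = rhs for symmetric M, falling back to the pseudoinverse
    when M is numerically singular.

    Rank deficiency of X'X (more covariates than objects) is routine and
    silent; a singular A'A in the regression step is worth a warning.
    """
    cond = np.linalg.cond(M) if M.size else np.inf
    if not np.isfinite(cond) or cond > 1e12:
        if warn:
            warnings.warn(
                f"singular normal equations in {what}; using pseudoinverse",
                stacklevel=3,
            )
        return np.linalg.pinv(M) @ rhs
    return np.linalg.solve(M, rhs)


def _regression_step(
    A: np.ndarray, X: np.ndarray, Y_A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional update of (P_X, G) given the component matrices."""
    AtA = A.T @ A
    PXt = _pinv_solve(AtA, A.T @ X, "P_X update")
    G_A = _pinv_solve(AtA, A.T @ Y_A @ np.kron(C, B), "core update")
    R1, R2, R3 = A.shape[1], B.shape[1], C.shape[1]
    G = G_A.reshape(R1, R3, R2).transpose(0, 2, 1)  # invert mode-A matricization
    return PXt.T, G


def _procrustes(F: np.ndarray) -> np.ndarray:
    """Orthonormal-column matrix maximizing tr(B'F) (polar factor of F)."""
    U, _, Vt = np.linalg.svd(F, full_matrices=False)
    return U @ Vt


def als_step(
    state: AlsState, X: np.ndarray, Y: np.ndarray, alpha: float
) -> AlsState:
    """One full ALS cycle (W-step, B-step, C-step, regression step)."""
    Y_A, Y_B, Y_C = unfold(Y, "A"), unfold(Y, "B"), unfold(Y, "C")
    beta = beta_from_alpha(alpha, X, Y_A)

    # (1) W-step: A = X W with W minimizing ||Q - X W S'||^2.
    Q, S = build_concatenation(X, Y_A, state.B, state.C, state.G, state.P_X, beta)
    XtX = X.T @ X
    StS = S.T @ S
    M = _pinv_solve(XtX, X.T @ Q @ S, "W update", warn=False)
    W = _pinv_solve(StS, M.T, "W update", warn=False).T
    A = X @ W

    # (2) B-step: orthonormal Procrustes against Y_B (C (x) A) G_B'.
    G_B = unfold_core(state.G, "B")
    B = _procrustes(Y_B @ np.kron(state.C, A) @ G_B.T)

    # (3) C-step: same construction in the source mode.
    G_C = unfold_core(state.G, "C")
    C = _procrustes(Y_C @ np.kron(B, A) @ G_C.T)

    # (4) regression step for the core and the predictor loadings.
    P_X, G = _regression_step(A, X, Y_A, B, C)
    return AlsState(W=W, A=A, B=B, C=C, G=G, P_X=P_X)


def _project_initial(
    A0: np.ndarray,
    B0: np.ndarray,
    C0: np.ndarray,
    X: np.ndarray,
    Y_A: np.ndarray,
    alpha: float,
) -> AlsState:
    """Complete an (A0, B0, C0) start into a full state with A in the column
    space of X, so the recorded loss history starts at a feasible point."""
    P_X, G = _regression_step(A0, X, Y_A, B0, C0)
    beta = beta_from_alpha(alpha, X, Y_A)
    Q, S = build_concatenation(X, Y_A, B0, C0, G, P_X, beta)
    M = _pinv_solve(X.T @ X, X.T @ Q @ S, "initial W", warn=False)
    W = _pinv_solve(S.T @ S, M.T, "initial W", warn=False).T
    A = X @ W
    P_X, G = _regression_step(A, X, Y_A, B0, C0)
    return AlsState(W=W, A=A, B=B0, C=C0, G=G, P_X=P_X)


def _run_single_start(
    A0, B0, C0, X, Y, alpha, tol, max_iter
) -> tuple[AlsState, np.ndarray, bool]:
    Y_A = unfold(Y, "A")
    state = _project_initial(A0, B0, C0, X, Y_A, alpha)
    history = [eq_loss(state.A, state.B, state.C, state.G, state.P_X, alpha, X, Y_A)]
    converged = False
    for _ in range(max_iter):
        state = als_step(state, X, Y, alpha)
        cur = eq_loss(state.A, state.B, state.C, state.G, state.P_X, alpha, X, Y_A)
        prev = history[-1]
        history.append(cur)
        if prev - cur <= tol * max(prev, 1e-30):
            converged = True
            break
    return state, np.asarray(history), converged


def _apply_sign_convention(state: AlsState) -> AlsState:
    """Per-column reflections so the largest-absolute entry of each B, C and A
    column is positive; the core (and P_X, W for A) absorbs the flips, leaving
    all fitted values unchanged."""
    B, C, G = state.B.copy(), state.C.copy(), state.G.copy()
    A, W, P_X = state.A.copy(), state.W.copy(), state.P_X.copy()
    for r in range(B.shape[1]):
        if B[np.argmax(np.abs(B[:, r])), r] < 0:
            B[:, r] *= -1
            G[:, r, :] *= -1
    for r in range(C.shape[1]):
        if C[np.argmax(np.abs(C[:, r])), r] < 0:
            C[:, r] *= -1
            G[:, :, r] *= -1
    for r in range(A.shape[1]):
        if A[np.argmax(np.abs(A[:, r])), r] < 0:
            A[:, r] *= -1
            W[:, r] *= -1
            P_X[:, r] *= -1
            G[r, :, :] *= -1
    return AlsState(W=W, A=A, B=B, C=C, G=G, P_X=P_X)


def fit(dataset: CoupledDataset, config: FitConfig, preprocess=None) -> Tucker3PCovRFit:
    """Multi-start ALS fit of the Tucker3-PCovR model.

    ``dataset`` is expected to hold preprocessed blocks (see
    :mod:`.preprocessing`); the loss normalizations use exactly the matrices
    entering the fit.  The first start is rational, the remaining
    ``config.n_starts - 1`` follow ``config.init``; the lowest final loss
    wins.  Component signs are normalized afterwards so repeated runs with
    the same seed are reproducible up to the model's intrinsic rotational
    indeterminacy.
    """
    X, Y = dataset.X, dataset.Y
    I, J, K, L = dataset.shape
    config.ranks.validate_for(I, J, K, L)
    Y_A = unfold(Y, "A")

    rational = init_rational(X, Y, config.ranks)
    extra_kind = "random" if config.init == "random" else "perturbed"
    streams = np.random.SeedSequence(config.seed).spawn(max(config.n_starts - 1, 0))

    best: tuple[AlsState, np.ndarray, bool] | None = None
    start_log = []
    for s in range(config.n_starts):
        if s == 0:
            A0, B0, C0 = rational
            kind = "rational"
        else:
            rng = np.random.default_rng(streams[s - 1])
            kind = extra_kind
            if kind == "random":
                A0, B0, C0 = init_random((I, J, K), config.ranks, rng)
            else:
                A0, B0, C0 = init_perturbed(rational, config.perturb_scale, rng)
        state, history, converged = _run_single_start(
            A0, B0, C0, X, Y, config.alpha, config.tol, config.max_iter
        )
        start_log.append(
            {
                "start": s,
                "init": kind,
                "iterations": len(history) - 1,
                "loss": float(history[-1]),
                "converged": bool(converged),
            }
        )
        if best is None or history[-1] < best[1][-1]:
            best = (state, history, converged)

    state, history, converged = best
    state = _apply_sign_convention(state)
    beta = beta_from_alpha(config.alpha, X, Y_A)
    return Tucker3PCovRFit(
        A=state.A,
        B=state.B,
        C=state.C,
        G=state.G,
        P_X=state.P_X,
        W_X=state.W,
        alpha=config.alpha,
        beta=beta,
        ranks=config.ranks,
        loss_history=history,
        converged=converged,
        n_iter=len(history) - 1,
        X=X,
        Y_A=Y_A,
        dataset=dataset,
        preprocess=preprocess,
        meta={"seed": config.seed, "n_starts": config.n_starts,
              "init": config.init, "starts": start_log},
    )
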