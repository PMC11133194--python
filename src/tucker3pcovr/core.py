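"""Core containers and algebra for Tucker3 principal covariates regression.

The model couples a two-way predictor block ``X`` (I objects x L covariates)
with a three-way criterion block ``Y`` (I objects x J attributes x K sources)
through a shared object-mode component matrix::

    X   = A P_X' + E_X,          A = X W_X          (I x R1 scores)
    Y_A = A G_A (C (x) B)' + E_A                    (Tucker3-structured fit)

where ``Y_A`` is the object-mode matricization of ``Y``, ``B`` (J x R2) and
``C`` (K x R3) carry orthonormal attribute and source components, and ``G``
is the R1 x R2 x R3 core array of interaction weights.  The estimation
criterion blends reconstruction of X and prediction of Y with a weight
``alpha`` in [0, 1].

Matricization convention
------------------------
Mode-A unfolding maps entry (i, j, k) to column ``k*J + j`` (0-based;
attribute index fastest), so that the columns of ``Y_A`` align with the rows
of the Kronecker product ``C (x) B``.  The core is matricized the same way:
``G_A`` is R1 x (R2*R3) with column ``r3*R2 + r2``.  Everything downstream
(prediction, ALS updates, biplot markers) relies on this single convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoupledDataset",
    "Ranks",
    "Tucker3PCovRFit",
    "unfold",
    "fold",
    "unfold_core",
    "fold_core",
    "predict_y",
    "predict_x",
    "beta_from_alpha",
    "loss",
    "concatenated_loss",
    "loss_proportionality_constant",
]

_MODE_AXES = {"A": 0, "B": 1, "C": 2}


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class CoupledDataset:
    """A predictor matrix and criterion array sharing their object mode.

    Parameters
    ----------
    X : (I, L) array
        Predictor block, objects by covariates.
    Y : (I, J, K) array
        Criterion block, objects by attributes by sources.
    object_labels, covariate_labels, attribute_labels, source_labels
        Optional mode labels; defaults are generated (``obj1``, ``x1``,
        ``attr1``, ``src1`` ...).
    """

    X: np.ndarray
    Y: np.ndarray
    object_labels: tuple[str, ...] = ()
    covariate_labels: tuple[str, ...] = ()
    attribute_labels: tuple[str, ...] = ()
    source_labels: tuple[str, ...] = ()

    def __post_init__(self):
        X = _as_float_array(self.X, "X", 2)
        Y = _as_float_array(self.Y, "Y", 3)
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"X and Y must share the object mode: X has {X.shape[0]} rows, "
                f"Y has {Y.shape[0]}"
            )
        if X.shape[0] < 2:
            raise ValueError("at least 2 objects are required")
        if min(X.shape + Y.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        I, L = X.shape
        _, J, K = Y.shape
        defaults = {
            "object_labels": (I, "obj"),
            "covariate_labels": (L, "x"),
            "attribute_labels": (J, "attr"),
            "source_labels": (K, "src"),
        }
        for name, (n, prefix) in defaults.items():
            labels = tuple(getattr(self, name))
            if not labels:
                labels = tuple(f"{prefix}{i + 1}" for i in range(n))
            elif len(labels) != n:
                raise ValueError(f"{name} has {len(labels)} entries, expected {n}")
            object.__setattr__(self, name, labels)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        """(I, J, K, L)."""
        return (self.X.shape[0], self.Y.shape[1], self.Y.shape[2], self.X.shape[1])

    @property
    def Y_A(self) -> np.ndarray:
        return unfold(self.Y, "A")


@dataclass(frozen=True)
class Ranks:
    """Tucker3 complexity (R1, R2, R3) with the usual validity constraints."""

    R1: int
    R2: int
    R3: int

    def __post_init__(self):
        for name in ("R1", "R2", "R3"):
            r = getattr(self, name)
            if not isinstance(r, (int, np.integer)) or r < 1:
                raise ValueError(f"{name} must be a positive integer, got {r!r}")
        r1, r2, r3 = self.R1, self.R2, self.R3
        if r1 > r2 * r3 or r2 > r1 * r3 or r3 > r1 * r2:
            raise ValueError(
                f"invalid Tucker3 complexity ({r1},{r2},{r3}): each rank must "
                "not exceed the product of the other two"
            )

    def validate_for(self, I: int, J: int, K: int, L: int) -> None:
        """Check the ranks against dataset dimensions (raises on violation)."""
        if self.R1 > min(I, L + J * K):
            raise ValueError(
                f"R1={self.R1} exceeds min(I, L + J*K) = {min(I, L + J * K)}"
            )
        if self.R2 > J:
            raise ValueError(f"R2={self.R2} exceeds J={J}")
        if self.R3 > K:
            raise ValueError(f"R3={self.R3} exceeds K={K}")

    def astuple(self) -> tuple[int, int, int]:
        return (self.R1, self.R2, self.R3)

    @property
    def complexity(self) -> int:
        return self.R1 + self.R2 + self.R3


def unfold(Y: np.ndarray, mode: str) -> np.ndarray:
    """Matricize a three-way array along one mode.

    Mode ``"A"`` gives I x JK with column ``k*J + j`` (attribute fastest),
    mode ``"B"`` gives J x IK with column ``k*I + i``, and mode ``"C"`` gives
    K x IJ with column ``j*I + i`` (all 0-based).  With this ordering the
    columns of the mode-A unfolding line up with the rows of ``C (x) B``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise ValueError(f"expected a 3-way array, got shape {Y.shape}")
    if mode == "A":
        # (I, J, K) -> (I, K, J) -> I x KJ, column k*J + j
        return Y.transpose(0, 2, 1).reshape(Y.shape[0], -1)
    if mode == "B":
        return Y.transpose(1, 2, 0).reshape(Y.shape[1], -1)
    if mode == "C":
        return Y.transpose(2, 1, 0).reshape(Y.shape[2], -1)
    raise ValueError(f"unknown mode {mode!r}; expected 'A', 'B' or 'C'")


def fold(M: np.ndarray, mode: str, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild the (I, J, K) array."""
    M = np.asarray(M, dtype=float)
    I, J, K = shape
    if mode == "A":
        return M.reshape(I, K, J).transpose(0, 2, 1)
    if mode == "B":
        return M.reshape(J, K, I).transpose(2, 0, 1)
    if mode == "C":
        return M.reshape(K, J, I).transpose(2, 1, 0)
    raise ValueError(f"unknown mode {mode!r}; expected 'A', 'B' or 'C'")


def unfold_core(G: np.ndarray, mode: str = "A") -> np.ndarray:
    """Matricize the core array with the same column ordering as :func:`unfold`."""
    return unfold(G, mode)


def fold_core(M: np.ndarray, mode: str, ranks: Ranks) -> np.ndarray:
    return fold(M, mode, ranks.astuple())


def predict_y(A: np.ndarray, G: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Fitted criterion block ``A G_A (C (x) B)'`` as an I x JK matrix.

    ``G`` may be passed as the 3-way core (R1, R2, R3) or already matricized
    as ``G_A`` (R1, R2*R3).
    """
    A = np.asarray(A, dtype=float)
    G = np.asarray(G, dtype=float)
    B = np.asarray(B, dtype=float)
    C = np.asarray(C, dtype=float)
    G_A = unfold_core(G, "A") if G.ndim == 3 else G
    R2, R3 = B.shape[1], C.shape[1]
    if A.shape[1] != G_A.shape[0] or G_A.shape[1] != R2 * R3:
        raise ValueError(
            f"shape mismatch: A {A.shape}, G_A {G_A.shape}, B {B.shape}, C {C.shape}"
        )
    return A @ G_A @ np.kron(C, B).T


def predict_x(A: np.ndarray, P_X: np.ndarray) -> np.ndarray:
    """Fitted predictor block ``A P_X'``."""
    return np.asarray(A, float) @ np.asarray(P_X, float).T


def beta_from_alpha(alpha: float, X: np.ndarray, Y_A: np.ndarray) -> float:
    """Map the user weight ``alpha`` to the unnormalized-loss weight ``beta``.

    beta = alpha ||Y_A||^2 / (alpha ||Y_A||^2 + (1 - alpha) ||X||^2),
    with Frobenius norms.  beta shares alpha's endpoints and is strictly
    increasing in alpha for fixed norms.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    ssx = float(np.sum(np.asarray(X, float) ** 2))
    ssy = float(np.sum(np.asarray(Y_A, float) ** 2))
    if ssx <= 0.0 or ssy <= 0.0:
        raise ValueError("both blocks must have positive Frobenius norm")
    return alpha * ssy / (alpha * ssy + (1.0 - alpha) * ssx)


def loss(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    G: np.ndarray,
    P_X: np.ndarray,
    alpha: float,
    X: np.ndarray,
    Y_A: np.ndarray,
) -> float:
    """Normalized Tucker3-PCovR loss.

    ``alpha * ||X - A P_X'||^2 / ||X||^2
    + (1 - alpha) * ||Y_A - A G_A (C (x) B)'||^2 / ||Y_A||^2``.
    """
    X = np.asarray(X, float)
    Y_A = np.asarray(Y_A, float)
    ssx = float(np.sum(X**2))
    ssy = float(np.sum(Y_A**2))
    if ssx <= 0.0 or ssy <= 0.0:
        raise ValueError("both blocks must have positive Frobenius norm")
    rx = float(np.sum((X - predict_x(A, P_X)) ** 2))
    ry = float(np.sum((Y_A - predict_y(A, G, B, C)) ** 2))
    return alpha * rx / ssx + (1.0 - alpha) * ry / ssy


def concatenated_loss(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    G: np.ndarray,
    P_X: np.ndarray,
    alpha: float,
    X: np.ndarray,
    Y_A: np.ndarray,
) -> float:
    """Unnormalized loss ``||Q - A S'||^2`` on the concatenated blocks.

    ``Q = [sqrt(beta) X | sqrt(1-beta) Y_A]`` and
    ``S' = [sqrt(beta) P_X' | sqrt(1-beta) G_A (C (x) B)']``.  Proportional
    to :func:`loss` by :func:`loss_proportionality_constant`; the ALS updates
    work on this form, results are reported on the normalized scale.
    """
    beta = beta_from_alpha(alpha, X, Y_A)
    Q, S = build_concatenation(X, Y_A, B, C, G, P_X, beta)
    return float(np.sum((Q - np.asarray(A, float) @ S.T) ** 2))


def build_concatenation(
    X: np.ndarray,
    Y_A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    G: np.ndarray,
    P_X: np.ndarray,
    beta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """The weighted concatenations Q (I x (L+JK)) and S ((L+JK) x R1)."""
    sb, sy = np.sqrt(beta), np.sqrt(1.0 - beta)
    G_A = unfold_core(np.asarray(G, float), "A") if np.asarray(G).ndim == 3 else np.asarray(G, float)
    P_Y = (G_A @ np.kron(np.asarray(C, float), np.asarray(B, float)).T).T
    Q = np.hstack([sb * np.asarray(X, float), sy * np.asarray(Y_A, float)])
    S = np.vstack([sb * np.asarray(P_X, float), sy * P_Y])
    return Q, S


def loss_proportionality_constant(alpha: float, X: np.ndarray, Y_A: np.ndarray) -> float:
    """Constant c with ``loss = c * concatenated_loss``.

    The normalized form weights the X-residual by alpha/||X||^2 while the
    concatenated form weights it by beta, so
    c = (alpha/||X||^2)/beta = (alpha ||Y_A||^2 + (1-alpha) ||X||^2)
    / (||X||^2 ||Y_A||^2), which also matches the Y-side ratio.
    """
    ssx = float(np.sum(np.asarray(X, float) ** 2))
    ssy = float(np.sum(np.asarray(Y_A, float) ** 2))
    return (alpha * ssy + (1.0 - alpha) * ssx) / (ssx * ssy)


@dataclass
class Tucker3PCovRFit:
    """An estimated Tucker3-PCovR model.

    Holds the object scores ``A = X W_X``, orthonormal attribute/source
    components ``B`` and ``C``, the core ``G``, predictor loadings ``P_X``
    and weights ``W_X``, plus the loss trajectory of the winning start.
    The derived response loadings ``P_Y`` and fitted blocks are exposed as
    properties; the preprocessed blocks the model was fitted to are kept so
    the fit is self-contained for plotting and interpolation.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    G: np.ndarray
    P_X: np.ndarray
    W_X: np.ndarray
    alpha: float
    beta: float
    ranks: Ranks
    loss_history: np.ndarray
    converged: bool
    n_iter: int
    X: np.ndarray | None = None
    Y_A: np.ndarray | None = None
    dataset: "CoupledDataset | None" = None
    preprocess: object | None = None
    meta: dict = field(default_factory=dict)

    @property
    def loss(self) -> float:
        return float(self.loss_history[-1])

    @property
    def G_A(self) -> np.ndarray:
        return unfold_core(self.G, "A")

    @property
    def P_Y(self) -> np.ndarray:
        """Response loadings, JK x R1: ``(G_A (C (x) B)')'``."""
        return (self.G_A @ np.kron(self.C, self.B).T).T

    @property
    def Z(self) -> np.ndarray:
        """Regression weights of responses on raw-scale predictors, L x JK."""
        return self.W_X @ self.P_Y.T

    def fitted_x(self) -> np.ndarray:
        return predict_x(self.A, self.P_X)

    def fitted_y(self) -> np.ndarray:
        return predict_y(self.A, self.G, self.B, self.C)

    def residual_norms(self) -> tuple[float, float]:
        """Frobenius norms of (E_X, E_A) on the fitted (preprocessed) scale."""
        if self.X is None or self.Y_A is None:
            raise ValueError("fit does not carry its training data")
        ex = float(np.linalg.norm(self.X - self.fitted_x()))
        ea = float(np.linalg.norm(self.Y_A - self.fitted_y()))
        return ex, ea

    def copy(self) -> "Tucker3PCovRFit":
        return Tucker3PCovRFit(
            A=self.A.copy(),
            B=self.B.copy(),
            C=self.C.copy(),
            G=self.G.copy(),
            P_X=self.P_X.copy(),
            W_X=self.W_X.copy(),
            alpha=self.alpha,
            beta=self.beta,
            ranks=self.ranks,
            loss_history=np.array(self.loss_history, copy=True),
            converged=self.converged,
            n_iter=self.n_iter,
            X=None if self.X is None else self.X.copy(),
            Y_A=None if self.Y_A is None else self.Y_A.copy(),
            dataset=self.dataset,
            preprocess=self.preprocess,
            meta=dict(self.meta),
        )
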