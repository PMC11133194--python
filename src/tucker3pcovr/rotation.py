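"""Varimax rotation of component matrices with exact core counterrotation.

A Tucker3-PCovR solution is identified only up to orthogonal rotation of each
component matrix: rotating B (or C) is compensated by multiplying the core
along the matching mode with the transposed rotation, and rotating the
predictor loadings P_X drags the shared object scores A (and the weights W_X)
along so both block factorizations stay consistent.  All fitted values and
the loss are exactly invariant; rotation is purely an interpretability
post-processing.
"""

from __future__ import annotations

import numpy as np

from .core import Tucker3PCovRFit

__all__ = ["varimax", "rotate_fit"]


def varimax(
    M: np.ndarray,
    normalize: bool = True,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal rotation maximizing the varimax criterion.

    Returns ``(M @ T, T)``.  With ``normalize=True`` Kaiser row
    normalization is applied while searching for T and undone afterwards
    (row scaling commutes with the column rotation, so the rotated matrix is
    simply ``M @ T``).  A single-column input returns the identity rotation.
    """
    M = np.asarray(M, dtype=float)
    p, k = M.shape
    if k < 2:
        return M.copy(), np.eye(k)
    L = M.copy()
    if normalize:
        h = np.sqrt(np.sum(M**2, axis=1))
        h[h == 0] = 1.0
        L = M / h[:, None]
    # classical pairwise sweeps with the closed-form Kaiser angle; exact for
    # each column pair, so it cannot stall on symmetric configurations
    T = np.eye(k)
    for _ in range(max_iter):
        max_angle = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (p * np.sum(u * v) - np.sum(u) * np.sum(v))
                den = p * np.sum(u**2 - v**2) - (np.sum(u) ** 2 - np.sum(v) ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < tol:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ rot
                T[:, [i, j]] = T[:, [i, j]] @ rot
        if max_angle < tol:
            break
    return M @ T, T


def varimax_criterion(M: np.ndarray) -> float:
    """The raw varimax objective: sum over columns of the variance of the
    squared loadings."""
    M2 = np.asarray(M, dtype=float) ** 2
    return float(np.sum(np.var(M2, axis=0)))


def _rotate_core(G: np.ndarray, T: np.ndarray, mode: str) -> np.ndarray:
    """Counterrotate the core along one mode (multiply by T' in that mode)."""
    if mode == "A":
        return np.einsum("abc,ad->dbc", G, T)
    if mode == "B":
        return np.einsum("abc,bd->adc", G, T)
    if mode == "C":
        return np.einsum("abc,cd->abd", G, T)
    raise ValueError(f"unknown core mode {mode!r}")


def rotate_fit(
    fit: Tucker3PCovRFit,
    modes=("B", "C", "PX"),
    rotations: dict[str, np.ndarray] | None = None,
    normalize: bool = True,
) -> Tucker3PCovRFit:
    """Rotate selected component matrices of a fit, counterrotating the core.

    ``modes`` is a subset of ``{"B", "C", "PX"}``.  For each mode a varimax
    rotation of the corresponding matrix is used unless an explicit
    orthogonal matrix is supplied in ``rotations``.  Rotating ``PX`` applies
    the same rotation to P_X, A and W_X and counterrotates the core along the
    object mode, so the shared first-mode factorization of both blocks stays
    consistent.  Fitted values and the loss are unchanged.
    """
    out = fit.copy()
    rotations = rotations or {}
    for mode in modes:
        if mode == "B":
            T = rotations.get("B")
            if T is None:
                _, T = varimax(out.B, normalize=normalize)
            out.B = out.B @ T
            out.G = _rotate_core(out.G, T, "B")
        elif mode == "C":
            T = rotations.get("C")
            if T is None:
                _, T = varimax(out.C, normalize=normalize)
            out.C = out.C @ T
            out.G = _rotate_core(out.G, T, "C")
        elif mode == "PX":
            T = rotations.get("PX")
            if T is None:
                _, T = varimax(out.P_X, normalize=normalize)
            out.P_X = out.P_X @ T
            out.A = out.A @ T
            out.W_X = out.W_X @ T
            out.G = _rotate_core(out.G, T, "A")
        else:
            raise ValueError(f"unknown rotation mode {mode!r}; expected B, C or PX")
        out.meta.setdefault("rotations", []).append(mode)
    return out
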