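"""Biplot coordinate engines for Tucker3-PCovR fits.

Every construction here is an exact factorization of a model matrix into row
and column markers whose inner products reproduce that matrix in full
dimension; plots are its rank-2 truncation (first two marker columns).

* **joint biplot** — per component r of a reference mode, the SVD of the core
  slice G_r splits ``A G_r B'`` into markers for the two display modes, with
  fourth-root level-count factors balancing marker sizes.
* **interactive biplot** — object markers A against JK interactively coded
  response markers (rows of P_Y); inner products reproduce the fitted Y_A.
* **triplot** — the interactive biplot plus predictor markers P_X, so objects,
  predictors and responses share one display; A P_X' reproduces the fitted X.
* **regression-weight biplot** — predictor weights W_X against response
  markers; inner products give the regression weights Z = W_X P_Y' of each
  response on each raw-scale predictor.
* **interpolation** — a new predictor profile x (raw units) is placed at
  a = x' W_X after applying the stored preprocessing, from which response
  predictions follow as a P_Y'.

Graded axis scales place ticks mu * w along a marker direction and label them
with the original-units value mean + sd * mu, so predictions can be read off
the display in the data's own units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Tucker3PCovRFit

__all__ = [
    "BiplotCoords",
    "joint_biplot",
    "interactive_biplot",
    "triplot",
    "regression_weight_biplot",
    "interpolate",
    "axis_scale_markers",
    "response_label",
]


@dataclass
class BiplotCoords:
    """Marker coordinates for one biplot.

    ``row_markers``/``col_markers`` (and ``pred_markers`` for triplots) map
    labels to full-dimensional coordinate vectors; 2-D display coordinates
    are their first two entries (:meth:`rows_2d` and friends).
    ``axis_scales`` maps a marker label to graded-scale ticks
    ``(2-vector, original-units value)``.
    """

    kind: str
    row_markers: dict[str, np.ndarray]
    col_markers: dict[str, np.ndarray]
    pred_markers: dict[str, np.ndarray] = field(default_factory=dict)
    axis_scales: dict[str, list[tuple[np.ndarray, float]]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def _to_2d(self, markers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for k, v in markers.items():
            v = np.atleast_1d(np.asarray(v, float))
            out[k] = np.pad(v, (0, max(0, 2 - v.size)))[:2]
        return out

    def rows_2d(self) -> dict[str, np.ndarray]:
        return self._to_2d(self.row_markers)

    def cols_2d(self) -> dict[str, np.ndarray]:
        return self._to_2d(self.col_markers)

    def preds_2d(self) -> dict[str, np.ndarray]:
        return self._to_2d(self.pred_markers)

    def inner_products(self, which: str = "col") -> np.ndarray:
        """Full-dimensional inner-product matrix rows x (cols|preds)."""
        R = np.array(list(self.row_markers.values()))
        other = self.col_markers if which == "col" else self.pred_markers
        Cm = np.array(list(other.values()))
        return R @ Cm.T

    def as_frame(self):
        """All markers as a tidy DataFrame (set, label, dim1, dim2, ...)."""
        import pandas as pd

        rows = []
        for set_name, markers in (
            ("row", self.row_markers),
            ("col", self.col_markers),
            ("pred", self.pred_markers),
        ):
            for label, v in markers.items():
                v = np.atleast_1d(np.asarray(v, float))
                rows.append(
                    {"set": set_name, "label": label,
                     **{f"dim{i + 1}": x for i, x in enumerate(v)}}
                )
        return pd.DataFrame(rows)


def response_label(j: int, k: int) -> str:
    """Interactively coded label for attribute j under source k (0-based in,
    1-based out): source index then attribute index, e.g. ``S2RP5``."""
    return f"S{k + 1}RP{j + 1}"


def _labels(fit: Tucker3PCovRFit, mode: str) -> list[str]:
    ds = fit.dataset
    n = {"A": fit.A.shape[0], "B": fit.B.shape[0], "C": fit.C.shape[0],
         "X": fit.P_X.shape[0]}[mode]
    if ds is not None:
        got = {
            "A": ds.object_labels,
            "B": ds.attribute_labels,
            "C": ds.source_labels,
            "X": ds.covariate_labels,
        }[mode]
        if len(got) == n:
            return list(got)
    prefix = {"A": "obj", "B": "attr", "C": "src", "X": "x"}[mode]
    return [f"{prefix}{i + 1}" for i in range(n)]


_JOINT_SETUP = {
    # reference mode -> (display modes, core slicer)
    "C": (("A", "B"), lambda G, r: G[:, :, r]),
    "B": (("A", "C"), lambda G, r: G[:, r, :]),
    "A": (("B", "C"), lambda G, r: G[r, :, :]),
}


def joint_biplot(
    fit: Tucker3PCovRFit,
    reference: str = "C",
    r: int = 1,
    display: tuple[str, str] | None = None,
) -> BiplotCoords:
    """Joint biplot for component ``r`` (1-based) of the reference mode.

    The core slice G_r is decomposed as U Delta V'; the display-mode markers
    are ``(n1/n2)^(1/4) M1 U Delta^(1/2)`` and ``(n2/n1)^(1/4) M2 V
    Delta^(1/2)`` where M1, M2 are the display component matrices and n1, n2
    their level counts, so the marker product reconstructs ``M1 G_r M2'``
    exactly.
    """
    if reference not in _JOINT_SETUP:
        raise ValueError(f"unknown reference mode {reference!r}")
    default_display, slicer = _JOINT_SETUP[reference]
    ref_rank = {"A": fit.ranks.R1, "B": fit.ranks.R2, "C": fit.ranks.R3}[reference]
    if not 1 <= r <= ref_rank:
        raise ValueError(f"component index r={r} out of range 1..{ref_rank}")
    display = tuple(display) if display is not None else default_display
    if sorted(display) != sorted(default_display):
        raise ValueError(
            f"display modes {display} must be the two modes other than the "
            f"reference {reference!r}"
        )
    mats = {"A": fit.A, "B": fit.B, "C": fit.C}
    G_r = slicer(fit.G, r - 1)
    if display != default_display:
        G_r = G_r.T
    M1, M2 = mats[display[0]], mats[display[1]]
    n1, n2 = M1.shape[0], M2.shape[0]
    U, s, Vt = np.linalg.svd(G_r, full_matrices=False)
    half = np.sqrt(s)
    A_star = (n1 / n2) ** 0.25 * M1 @ U * half
    B_star = (n2 / n1) ** 0.25 * M2 @ Vt.T * half
    return BiplotCoords(
        kind="joint",
        row_markers=dict(zip(_labels(fit, display[0]), A_star)),
        col_markers=dict(zip(_labels(fit, display[1]), B_star)),
        meta={"reference": reference, "r": r, "display": display,
              "singular_values": s},
    )


def interactive_biplot(
    fit: Tucker3PCovRFit,
    attribute: int | str | None = None,
    source: int | str | None = None,
) -> BiplotCoords:
    """Interactive biplot: object markers A against JK response markers P_Y.

    Full-dimensional inner products reproduce the fitted Y_A.  ``attribute``
    or ``source`` (index or label) restricts the column markers to one
    attribute across all sources, or one source across all attributes.
    """
    attr_labels = _labels(fit, "B")
    src_labels = _labels(fit, "C")
    j_sel = _resolve(attribute, attr_labels, "attribute")
    k_sel = _resolve(source, src_labels, "source")
    P_Y = fit.P_Y  # JK x R1, row k*J + j
    J = len(attr_labels)
    cols = {}
    for k in range(len(src_labels)):
        if k_sel is not None and k != k_sel:
            continue
        for j in range(J):
            if j_sel is not None and j != j_sel:
                continue
            cols[response_label(j, k)] = P_Y[k * J + j]
    return BiplotCoords(
        kind="interactive",
        row_markers=dict(zip(_labels(fit, "A"), fit.A)),
        col_markers=cols,
        meta={"attribute": attribute, "source": source},
    )


def _resolve(sel, labels: list[str], what: str) -> int | None:
    if sel is None:
        return None
    if isinstance(sel, str):
        if sel not in labels:
            raise ValueError(f"unknown {what} label {sel!r}")
        return labels.index(sel)
    if not 0 <= int(sel) < len(labels):
        raise ValueError(f"{what} index {sel} out of range")
    return int(sel)


def triplot(fit: Tucker3PCovRFit, **kwargs) -> BiplotCoords:
    """Simultaneous display of objects (A), predictors (P_X) and responses
    (P_Y); A P_X' reproduces the fitted X and A P_Y' the fitted Y_A."""
    coords = interactive_biplot(fit, **kwargs)
    coords.kind = "triplot"
    coords.pred_markers = dict(zip(_labels(fit, "X"), fit.P_X))
    return coords


def regression_weight_biplot(fit: Tucker3PCovRFit) -> BiplotCoords:
    """Biplot of the regression weights Z = W_X P_Y'.

    Predictor markers are rows of W_X and response markers rows of P_Y;
    their inner products are the weights of each (preprocessed-scale)
    predictor in predicting each response at each source, and X Z equals the
    fitted Y_A.
    """
    inter = interactive_biplot(fit)
    return BiplotCoords(
        kind="regression_weight",
        row_markers=dict(zip(_labels(fit, "X"), fit.W_X)),
        col_markers=inter.col_markers,
    )


def interpolate(
    fit: Tucker3PCovRFit,
    x_new: np.ndarray,
    raw: bool = True,
    return_predictions: bool = False,
):
    """Project a new predictor profile onto the object-score space.

    ``a = x' W_X`` after transforming ``x_new`` with the stored
    preprocessing (``raw=True``); a training row therefore lands exactly on
    its own score row, and the raw predictor means land at the origin.  With
    ``return_predictions=True`` also returns the response predictions
    ``a P_Y'`` (fitted scale).
    """
    x = np.asarray(x_new, dtype=float).ravel()
    if x.size != fit.W_X.shape[0]:
        raise ValueError(
            f"x_new has length {x.size}, expected {fit.W_X.shape[0]} predictors"
        )
    if raw:
        if fit.preprocess is None:
            raise ValueError(
                "fit carries no preprocessing info; pass raw=False with an "
                "already-transformed profile"
            )
        x = fit.preprocess.transform_x(x[None, :]).ravel()
    a = x @ fit.W_X
    if return_predictions:
        return a, a @ fit.P_Y.T
    return a


def axis_scale_markers(
    direction: np.ndarray,
    values,
    preprocess_info=None,
    variable: int | None = None,
) -> list[tuple[np.ndarray, float]]:
    """Graded-scale ticks along a marker direction.

    For each value mu (on the preprocessed scale) the tick sits at
    ``mu * direction`` (first two coordinates); the label is the
    original-units value ``mean + sd * mu`` of the given predictor when
    preprocessing info is supplied, else mu itself.  mu = 0 labels the
    variable's mean at the origin.
    """
    d = np.asarray(direction, dtype=float).ravel()[:2]
    if not np.any(d):
        raise ValueError("direction vector must be nonzero")
    mean = sd = None
    if preprocess_info is not None and variable is not None:
        if preprocess_info.x_mean is not None:
            mean = float(preprocess_info.x_mean[variable])
        if preprocess_info.x_scale is not None:
            sd = float(preprocess_info.x_scale[variable])
    ticks = []
    for mu in values:
        label = float(mu)
        if sd is not None:
            label *= sd
        if mean is not None:
            label += mean
        ticks.append((mu * d, label))
    return ticks


def plot_coords(coords: BiplotCoords, path=None, ax=None):
    """Minimal matplotlib rendering of a :class:`BiplotCoords` (optional)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 7))
    for label, v in coords.rows_2d().items():
        ax.scatter(*v, color="tab:blue", s=12)
        ax.annotate(label, v, fontsize=7, color="tab:blue")
    for label, v in coords.cols_2d().items():
        ax.arrow(0, 0, v[0], v[1], color="tab:red", head_width=0.0, alpha=0.6)
        ax.annotate(label, v, fontsize=7, color="tab:red")
    for label, v in coords.preds_2d().items():
        ax.arrow(0, 0, v[0], v[1], color="tab:green", head_width=0.0, alpha=0.6)
        ax.annotate(label, v, fontsize=7, color="tab:green")
    for _, ticks in coords.axis_scales.items():
        for tick, value in ticks:
            ax.scatter(*tick[:2], marker="+", color="gray", s=10)
            ax.annotate(f"{value:g}", tick[:2], fontsize=6, color="gray")
    ax.axhline(0, color="gray", lw=0.5)
    ax.axvline(0, color="gray", lw=0.5)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.set_title(f"{coords.kind} biplot")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
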