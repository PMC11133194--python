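"""Pre-processing of the coupled blocks.

Predictors are autoscaled column-wise (mean 0, standard deviation 1 with the
n-1 denominator).  The criterion array is centered across objects within each
(attribute, source) cell and then given unit pooled variance per attribute:
a single scale per attribute across all sources, so that profiles of the same
response measured under different sources remain comparable.  A per-cell
autoscaling variant is available via ``y_scale="attribute-source"``.

The fitted statistics are stored so new observations can be transformed
identically (required by the interpolation biplot) and so the transforms can
be inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CoupledDataset

__all__ = ["PreprocessInfo", "standardize_x", "preprocess_y", "preprocess_dataset"]


@dataclass
class PreprocessInfo:
    """Fitted centering/scaling statistics for one or both blocks."""

    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: np.ndarray | None = None  # (J, K) per-cell means
    y_scale: np.ndarray | None = None  # (J,) or (J, K) depending on mode
    y_scale_mode: str = "attribute"
    steps: dict = field(default_factory=dict)

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.x_mean is not None:
            X = X - self.x_mean
        if self.x_scale is not None:
            X = X / self.x_scale
        return X

    def inverse_transform_x(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.x_scale is not None:
            X = X * self.x_scale
        if self.x_mean is not None:
            X = X + self.x_mean
        return X

    def transform_y(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        if self.y_mean is not None:
            Y = Y - self.y_mean[None, :, :]
        if self.y_scale is not None:
            Y = Y / self._y_scale_cube()
        return Y

    def inverse_transform_y(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        if self.y_scale is not None:
            Y = Y * self._y_scale_cube()
        if self.y_mean is not None:
            Y = Y + self.y_mean[None, :, :]
        return Y

    def _y_scale_cube(self) -> np.ndarray:
        s = self.y_scale
        if s.ndim == 1:  # one scale per attribute, broadcast over sources
            return s[None, :, None]
        return s[None, :, :]


def standardize_x(
    X: np.ndarray,
    center: bool = True,
    scale: bool = True,
    labels: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, PreprocessInfo]:
    """Column-wise autoscaling of the predictor block (ddof=1)."""
    X = np.asarray(X, dtype=float)
    info = PreprocessInfo(steps={"x_center": center, "x_scale": scale})
    if center:
        info.x_mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd <= 0)
        if bad.size:
            names = (
                [labels[i] for i in bad]
                if labels is not None
                else [f"column {i}" for i in bad]
            )
            raise ValueError(
                "cannot standardize zero-variance predictor(s): " + ", ".join(names)
            )
        info.x_scale = sd
    return info.transform_x(X), info


def preprocess_y(
    Y: np.ndarray,
    center: bool = True,
    scale: bool = True,
    scale_mode: str = "attribute",
    labels: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, PreprocessInfo]:
    """Center the criterion array across objects and normalize attributes.

    After centering, each attribute j is scaled so that
    ``sum_{i,k} y[i,j,k]^2 / (I*K - 1) = 1`` (``scale_mode="attribute"``), or
    each (j, k) cell is scaled to unit variance (``"attribute-source"``).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise ValueError(f"expected a 3-way array, got shape {Y.shape}")
    I, J, K = Y.shape
    if center and I < 2:
        raise ValueError("cannot center across objects with a single object")
    if scale_mode not in ("attribute", "attribute-source"):
        raise ValueError(f"unknown y scale mode {scale_mode!r}")
    info = PreprocessInfo(
        steps={"y_center": center, "y_scale": scale}, y_scale_mode=scale_mode
    )
    if center:
        info.y_mean = Y.mean(axis=0)
    Yc = info.transform_y(Y) if center else Y
    if scale:
        if scale_mode == "attribute":
            ss = np.sum(Yc**2, axis=(0, 2)) / (I * K - 1)
        else:
            ss = np.sum(Yc**2, axis=0) / (I - 1)
        s = np.sqrt(ss)
        bad = np.flatnonzero(np.ravel(s) <= 0)
        if bad.size:
            names = (
                [labels[i] for i in bad]
                if labels is not None and s.ndim == 1
                else [str(i) for i in bad]
            )
            raise ValueError(
                "attribute(s) with no variation after centering: " + ", ".join(names)
            )
        info.y_scale = s
    return info.transform_y(Y), info


def preprocess_dataset(
    dataset: CoupledDataset,
    center_x: bool = True,
    scale_x: bool = True,
    center_y: bool = True,
    y_scale: str = "attribute",
) -> tuple[CoupledDataset, PreprocessInfo]:
    """Apply the standard pre-processing to both blocks of a coupled dataset.

    ``y_scale`` is one of ``"attribute"``, ``"attribute-source"`` or
    ``"none"``.  Returns the transformed dataset and a single
    :class:`PreprocessInfo` carrying the statistics for both blocks.
    """
    Xp, info_x = standardize_x(
        dataset.X, center=center_x, scale=scale_x, labels=dataset.covariate_labels
    )
    scale_flag = y_scale != "none"
    mode = y_scale if scale_flag else "attribute"
    Yp, info_y = preprocess_y(
        dataset.Y,
        center=center_y,
        scale=scale_flag,
        scale_mode=mode,
        labels=dataset.attribute_labels,
    )
    info = PreprocessInfo(
        x_mean=info_x.x_mean,
        x_scale=info_x.x_scale,
        y_mean=info_y.y_mean,
        y_scale=info_y.y_scale,
        y_scale_mode=mode,
        steps={**info_x.steps, **info_y.steps},
    )
    out = CoupledDataset(
        X=Xp,
        Y=Yp,
        object_labels=dataset.object_labels,
        covariate_labels=dataset.covariate_labels,
        attribute_labels=dataset.attribute_labels,
        source_labels=dataset.source_labels,
    )
    return out, info
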