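"""Readers and writers for coupled datasets and fitted models.

Datasets travel as delimited text: the predictor block as a labeled CSV
matrix (objects in the first column), the criterion block either in long
format (``object,attribute,source,value``) or as K stacked I x J tables
(``source,object,<attribute columns>``).  A fitted model is a directory of
full-precision CSV matrices plus ``meta.json``; the core is serialized long
(``r1,r2,r3,value``) so no matricization convention is baked into the files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CoupledDataset, Ranks, Tucker3PCovRFit, unfold
from .preprocessing import PreprocessInfo

__all__ = [
    "read_coupled",
    "write_dataset",
    "write_fit",
    "read_fit",
]

_FLOAT_FMT = "%.17g"


def _read_x(x_path) -> pd.DataFrame:
    df = pd.read_csv(x_path, index_col=0, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"predictor file {x_path} is empty")
    df.index = df.index.astype(str)
    return df.astype(float)


def _read_y_long(y_path) -> pd.DataFrame:
    df = pd.read_csv(y_path, float_precision="round_trip")
    required = ["object", "attribute", "source", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"long-format criterion file {y_path} lacks column(s) {missing}; "
            f"expected header object,attribute,source,value"
        )
    for c in required[:3]:
        df[c] = df[c].astype(str)
    return df


def _read_y_stacked(y_path) -> pd.DataFrame:
    df = pd.read_csv(y_path, float_precision="round_trip")
    if df.columns[0] != "source" or df.columns[1] != "object":
        raise ValueError(
            f"stacked criterion file {y_path} must start with columns "
            "source,object followed by one column per attribute"
        )
    long = df.melt(id_vars=["source", "object"], var_name="attribute",
                   value_name="value")
    for c in ("object", "attribute", "source"):
        long[c] = long[c].astype(str)
    return long


def read_coupled(x_path, y_path, y_format: str = "long") -> CoupledDataset:
    """Load a coupled dataset, matching objects between blocks by label.

    Mode levels are ordered by first appearance in the files.  Duplicate or
    missing (object, attribute, source) cells and object sets that differ
    between the blocks are hard errors.
    """
    xdf = _read_x(x_path)
    if y_format == "long":
        ydf = _read_y_long(y_path)
    elif y_format == "stacked":
        ydf = _read_y_stacked(y_path)
    else:
        raise ValueError(f"unknown y_format {y_format!r}; expected long or stacked")

    objects = list(dict.fromkeys(ydf["object"]))
    attributes = list(dict.fromkeys(ydf["attribute"]))
    sources = list(dict.fromkeys(ydf["source"]))

    dup = ydf.duplicated(subset=["object", "attribute", "source"])
    if dup.any():
        row = ydf[dup].iloc[0]
        raise ValueError(
            f"duplicate criterion cell (object={row['object']}, "
            f"attribute={row['attribute']}, source={row['source']})"
        )
    if len(ydf) != len(objects) * len(attributes) * len(sources) or ydf[
        "value"
    ].isna().any():
        seen = set(zip(ydf.loc[ydf["value"].notna(), "object"],
                       ydf.loc[ydf["value"].notna(), "attribute"],
                       ydf.loc[ydf["value"].notna(), "source"]))
        for o in objects:
            for a in attributes:
                for s in sources:
                    if (o, a, s) not in seen:
                        raise ValueError(
                            f"missing criterion cell (object={o}, "
                            f"attribute={a}, source={s})"
                        )

    x_objects = list(xdf.index)
    if set(x_objects) != set(objects):
        only_x = sorted(set(x_objects) - set(objects))
        only_y = sorted(set(objects) - set(x_objects))
        raise ValueError(
            "object labels differ between blocks: "
            f"only in X: {only_x[:5]}; only in Y: {only_y[:5]}"
        )
    xdf = xdf.loc[objects]

    cube = (
        ydf.set_index(["object", "attribute", "source"])["value"]
        .astype(float)
        .unstack(["attribute", "source"])
        .loc[objects]
    )
    I, J, K = len(objects), len(attributes), len(sources)
    Y = np.empty((I, J, K))
    for j, a in enumerate(attributes):
        for k, s in enumerate(sources):
            Y[:, j, k] = cube[(a, s)].to_numpy()
    return CoupledDataset(
        X=xdf.to_numpy(),
        Y=Y,
        object_labels=tuple(objects),
        covariate_labels=tuple(map(str, xdf.columns)),
        attribute_labels=tuple(attributes),
        source_labels=tuple(sources),
    )


def write_dataset(dataset: CoupledDataset, x_path, y_path, y_format: str = "long") -> None:
    """Write a coupled dataset in the formats :func:`read_coupled` accepts."""
    xdf = pd.DataFrame(
        dataset.X, index=list(dataset.object_labels),
        columns=list(dataset.covariate_labels),
    )
    xdf.index.name = "object"
    xdf.to_csv(x_path, float_format=_FLOAT_FMT)
    I, J, K = dataset.Y.shape
    if y_format == "long":
        rows = [
            (dataset.object_labels[i], dataset.attribute_labels[j],
             dataset.source_labels[k], dataset.Y[i, j, k])
            for i in range(I) for j in range(J) for k in range(K)
        ]
        pd.DataFrame(rows, columns=["object", "attribute", "source", "value"]).to_csv(
            y_path, index=False, float_format=_FLOAT_FMT
        )
    elif y_format == "stacked":
        blocks = []
        for k in range(K):
            block = pd.DataFrame(
                dataset.Y[:, :, k], columns=list(dataset.attribute_labels)
            )
            block.insert(0, "object", list(dataset.object_labels))
            block.insert(0, "source", dataset.source_labels[k])
            blocks.append(block)
        pd.concat(blocks).to_csv(y_path, index=False, float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown y_format {y_format!r}")


def _write_matrix(M: np.ndarray, path: Path, index, columns) -> None:
    df = pd.DataFrame(M, index=list(index), columns=list(columns))
    df.index.name = "label"
    df.to_csv(path, float_format=_FLOAT_FMT)


def _read_matrix(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"fit directory is missing {path.name}")
    return pd.read_csv(path, index_col=0, float_precision="round_trip")


def write_fit(fit: Tucker3PCovRFit, out_dir) -> None:
    """Serialize a fit to a directory of CSV matrices plus meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = fit.ranks
    comp1 = [f"comp{i + 1}" for i in range(r.R1)]
    comp2 = [f"comp{i + 1}" for i in range(r.R2)]
    comp3 = [f"comp{i + 1}" for i in range(r.R3)]
    ds = fit.dataset
    obj = ds.object_labels if ds is not None else range(1, fit.A.shape[0] + 1)
    attr = ds.attribute_labels if ds is not None else range(1, fit.B.shape[0] + 1)
    src = ds.source_labels if ds is not None else range(1, fit.C.shape[0] + 1)
    cov = ds.covariate_labels if ds is not None else range(1, fit.P_X.shape[0] + 1)

    _write_matrix(fit.A, out / "A.csv", obj, comp1)
    _write_matrix(fit.B, out / "B.csv", attr, comp2)
    _write_matrix(fit.C, out / "C.csv", src, comp3)
    _write_matrix(fit.P_X, out / "PX.csv", cov, comp1)
    _write_matrix(fit.W_X, out / "WX.csv", cov, comp1)
    core_rows = [
        (r1 + 1, r2 + 1, r3 + 1, fit.G[r1, r2, r3])
        for r1 in range(r.R1) for r2 in range(r.R2) for r3 in range(r.R3)
    ]
    pd.DataFrame(core_rows, columns=["r1", "r2", "r3", "value"]).to_csv(
        out / "core.csv", index=False, float_format=_FLOAT_FMT
    )
    if fit.X is not None:
        _write_matrix(fit.X, out / "X.csv", obj, cov)
    if fit.Y_A is not None:
        ja_cols = [f"{a}|{s}" for s in src for a in attr]
        _write_matrix(fit.Y_A, out / "YA.csv", obj, ja_cols)
    from . import __version__

    meta = {
        "alpha": fit.alpha,
        "beta": fit.beta,
        "ranks": list(r.astuple()),
        "loss": fit.loss,
        "loss_history": [float(v) for v in fit.loss_history],
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "seed": fit.meta.get("seed"),
        "version": __version__,
        "starts": fit.meta.get("starts"),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    if fit.preprocess is not None:
        p = fit.preprocess
        pp = {
            "y_scale_mode": p.y_scale_mode,
            "steps": p.steps,
        }
        for name in ("x_mean", "x_scale", "y_mean", "y_scale"):
            v = getattr(p, name)
            pp[name] = None if v is None else np.asarray(v).tolist()
        (out / "preprocess.json").write_text(json.dumps(pp, indent=1))


def read_fit(fit_dir) -> Tucker3PCovRFit:
    """Load a fit written by :func:`write_fit` (lossless round trip)."""
    d = Path(fit_dir)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"fit directory is missing meta.json: {d}")
    meta = json.loads(meta_path.read_text())
    A = _read_matrix(d / "A.csv")
    B = _read_matrix(d / "B.csv")
    C = _read_matrix(d / "C.csv")
    P_X = _read_matrix(d / "PX.csv")
    W_X = _read_matrix(d / "WX.csv")
    core = pd.read_csv(d / "core.csv", float_precision="round_trip") if (d / "core.csv").exists() else None
    if core is None:
        raise FileNotFoundError(f"fit directory is missing core.csv: {d}")
    ranks = Ranks(*meta["ranks"])
    G = np.zeros(ranks.astuple())
    for _, row in core.iterrows():
        G[int(row.r1) - 1, int(row.r2) - 1, int(row.r3) - 1] = row.value

    X = Y_A = dataset = None
    if (d / "X.csv").exists() and (d / "YA.csv").exists():
        Xdf = _read_matrix(d / "X.csv")
        Ydf = _read_matrix(d / "YA.csv")
        X = Xdf.to_numpy(float)
        Y_A = Ydf.to_numpy(float)
        from .core import fold

        dataset = CoupledDataset(
            X=X,
            Y=fold(Y_A, "A", (X.shape[0], B.shape[0], C.shape[0])),
            object_labels=tuple(map(str, Xdf.index)),
            covariate_labels=tuple(map(str, Xdf.columns)),
            attribute_labels=tuple(map(str, B.index)),
            source_labels=tuple(map(str, C.index)),
        )

    preprocess = None
    pp_path = d / "preprocess.json"
    if pp_path.exists():
        pp = json.loads(pp_path.read_text())
        preprocess = PreprocessInfo(
            x_mean=None if pp["x_mean"] is None else np.asarray(pp["x_mean"]),
            x_scale=None if pp["x_scale"] is None else np.asarray(pp["x_scale"]),
            y_mean=None if pp["y_mean"] is None else np.asarray(pp["y_mean"]),
            y_scale=None if pp["y_scale"] is None else np.asarray(pp["y_scale"]),
            y_scale_mode=pp["y_scale_mode"],
            steps=pp["steps"],
        )

    return Tucker3PCovRFit(
        A=A.to_numpy(float),
        B=B.to_numpy(float),
        C=C.to_numpy(float),
        G=G,
        P_X=P_X.to_numpy(float),
        W_X=W_X.to_numpy(float),
        alpha=float(meta["alpha"]),
        beta=float(meta["beta"]),
        ranks=ranks,
        loss_history=np.asarray(meta["loss_history"], dtype=float),
        converged=bool(meta["converged"]),
        n_iter=int(meta["n_iter"]),
        X=X,
        Y_A=Y_A,
        dataset=dataset,
        preprocess=preprocess,
        meta={"seed": meta.get("seed"), "starts": meta.get("starts")},
    )
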