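"""Reading delimited data-sets and writing sampler output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import Dataset

__all__ = ["read_dataset", "write_dataset", "write_pips", "write_trace"]


def read_dataset(path, family: str, z_cols: Optional[Sequence[str]] = None,
                 sep: str = ",") -> Dataset:
    """Read a covariate/response table.

    The response is the column ``y`` (logistic) or the pair ``time``/``event``
    (survival); ``z_cols`` names the always-included covariates; every other
    column is a selectable covariate.
    """
    df = pd.read_csv(path, sep=sep)
    z_cols = list(z_cols or [])
    if family == "logistic":
        resp_cols = ["y"]
        y = df["y"].to_numpy(dtype=float)
        t = d = None
    else:
        resp_cols = ["time", "event"]
        y = None
        t = df["time"].to_numpy(dtype=float)
        d = df["event"].to_numpy(dtype=float)
    x_cols = [c for c in df.columns if c not in resp_cols + z_cols]
    X = df[x_cols].to_numpy(dtype=float)
    Z = df[z_cols].to_numpy(dtype=float) if z_cols else None
    return Dataset(X=X, Z=Z, y=y, t=t, d=d, family=family, names=x_cols)


def write_dataset(path, data: Dataset, truth: Optional[dict] = None) -> None:
    """Write data.csv (and truth.json next to it when a truth record is given)."""
    path = Path(path)
    cols = {}
    for i in range(data.q):
        cols[f"z{i}"] = data.Z[:, i]
    names = data.names or [f"x{j}" for j in range(data.p)]
    for j, name in enumerate(names):
        cols[name] = data.X[:, j]
    if data.family == "logistic":
        cols["y"] = data.y
    else:
        cols["time"] = data.t
        cols["event"] = data.d
    pd.DataFrame(cols).to_csv(path, index=False)
    if truth is not None:
        path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))


def write_pips(path, pips: np.ndarray, names: Optional[Sequence[str]] = None) -> None:
    names = names or [f"x{j}" for j in range(len(pips))]
    pd.DataFrame({"index": np.arange(len(pips)), "name": names,
                  "pip": pips}).to_csv(path, index=False)


def write_trace(path, output) -> None:
    pd.DataFrame({
        "iter": np.arange(len(output.log_post_trace)),
        "log_post": output.log_post_trace,
        "accepted": output.accept_flags.astype(int),
        "p_k": output.p_k_trace,
    }).to_csv(path, index=False)
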