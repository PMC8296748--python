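"""Readers, writers and manifests.

Formats are plain text: connectivity matrices as N x N CSV with region
ids as header and index, time series as TSV/CSV with a header row of
region ids, dataset manifests as CSV with columns
``sample_id, path, label``, masks as CSV, reports as JSON, run
configuration as YAML.  Floats are serialized with 17 significant digits
so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .graphs import (ConnectivityMatrix, GraphSample, TimeSeriesTable,
                     build_graph, pearson_connectivity)

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix", "write_matrix", "DatasetManifest", "load_dataset",
    "save_report", "load_config", "save_mask", "read_mask",
    "save_checkpoint", "load_checkpoint",
]

_SYM_TOL = 1e-8


def read_matrix(path) -> ConnectivityMatrix:
    """Load and validate a connectivity CSV.

    Small asymmetries (<= 1e-8) are symmetrized by averaging; larger ones
    and out-of-range or missing entries are rejected with the offending
    location.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is {m.shape}, expected square")
    if np.isnan(m).any():
        i, j = np.argwhere(np.isnan(m))[0]
        raise ValueError(f"{path}: NaN entry at row {i}, col {j}")
    bad = np.argwhere(np.abs(m) > 1 + _SYM_TOL)
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{path}: entry {m[i, j]} at row {i}, col {j} "
                         "outside [-1, 1]")
    asym = np.abs(m - m.T)
    if asym.max() > _SYM_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(f"{path}: asymmetry {asym[i, j]:.3g} at "
                         f"({i}, {j}) exceeds tolerance {_SYM_TOL}")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return ConnectivityMatrix(np.clip(m, -1.0, 1.0),
                              [str(c) for c in df.columns])


def write_matrix(cm: ConnectivityMatrix, path) -> None:
    df = pd.DataFrame(cm.rho, index=cm.region_ids, columns=cm.region_ids)
    df.to_csv(path, float_format="%.17g")


@dataclass
class DatasetManifest:
    """Rows of {sample_id, path, label} plus the payload format."""

    rows: pd.DataFrame
    root: Path
    format: str = "matrix_csv"  # or "timeseries_tsv"

    @classmethod
    def read(cls, path) -> "DatasetManifest":
        path = Path(path)
        df = pd.read_csv(path)
        required = {"sample_id", "path", "label"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"{path}: duplicate sample_id {dup!r}")
        if not set(df["label"].unique()) <= {0, 1}:
            raise ValueError(f"{path}: labels must be 0 or 1")
        fmt = "timeseries_tsv" if str(df["path"].iloc[0]).endswith(
            (".tsv", ".txt")) else "matrix_csv"
        return cls(rows=df, root=path.parent, format=fmt)

    def write(self, path) -> None:
        self.rows.to_csv(path, index=False)


def load_dataset(manifest: DatasetManifest | str | Path,
                 threshold: float | None = None) -> list[GraphSample]:
    """Load every manifest row as a GraphSample, in manifest order.

    Time-series files run through the Pearson construction pipeline;
    matrix files are validated and thresholded directly.  All samples
    must share the same node count.
    """
    if not isinstance(manifest, DatasetManifest):
        manifest = DatasetManifest.read(manifest)
    samples = []
    for row_num, row in enumerate(manifest.rows.itertuples(index=False)):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest.root / p
        if not p.exists():
            raise FileNotFoundError(
                f"manifest row {row_num} ({row.sample_id}): {p} not found")
        if manifest.format == "timeseries_tsv":
            cm = pearson_connectivity(
                TimeSeriesTable.from_file(p, sample_id=row.sample_id))
        else:
            cm = read_matrix(p)
        samples.append(build_graph(cm, int(row.label), threshold=threshold,
                                   sample_id=str(row.sample_id)))
    n_nodes = {s.n_nodes for s in samples}
    if len(n_nodes) > 1:
        raise ValueError(f"mixed node counts across samples: {sorted(n_nodes)}")
    return samples


def save_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)


KNOWN_CONFIG_KEYS = {
    "model", "training", "interpretation", "baseline", "seed", "out_dir",
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def save_mask(values: np.ndarray, path) -> None:
    pd.DataFrame(values).to_csv(path, index=False, float_format="%.17g")


def read_mask(path) -> np.ndarray:
    return pd.read_csv(path,
                       float_precision="round_trip").to_numpy(dtype=float)


def save_checkpoint(model, path) -> None:
    """Flat named-tensor archive (JSON of parameter arrays + model spec)."""
    payload = {
        "class": type(model).__name__,
        "n_nodes": model.n_nodes,
        "n_features": model.n_features,
        "params": [p.data.tolist() for p in model.parameters()],
    }
    for attr in ("_arch",):
        if hasattr(model, attr):
            payload["arch"] = getattr(model, attr)
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path, model) -> None:
    """Restore parameters saved by :func:`save_checkpoint` into a model
    built with the same architecture."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload["class"] != type(model).__name__:
        raise ValueError(f"checkpoint is for {payload['class']}, "
                         f"not {type(model).__name__}")
    values = [np.asarray(v, dtype=float) for v in payload["params"]]
    model.set_params(values)
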