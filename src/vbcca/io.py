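"""Readers and writers for time series, connectivity matrices, HRF kernels.

Conventions: time-series files are delimited text with T rows (time) and N
columns (regions), a header row of region names, and the sampling interval
(TR) carried in a JSON sidecar ``<path>.json`` or supplied explicitly.
Connectivity files are square matrices with region names on both axes;
rows are targets and columns are sources (cell (i, j) = influence j -> i).
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .hrf import HRFKernel

__all__ = [
    "load_timeseries",
    "save_timeseries",
    "load_connectivity",
    "save_connectivity",
    "load_hrf",
    "save_hrf",
    "load_edge_list",
    "save_edge_list",
    "RunManifest",
    "write_manifest",
]

_SEP = "\t"


def _validate_numeric(frame: pd.DataFrame, path) -> None:
    if frame.empty:
        raise ValueError(f"{path}: empty table")
    bad = frame.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at row {r + 1}, column {frame.columns[c]!r}"
        )


def load_timeseries(path, tr: float | None = None):
    """Read a (T rows x N columns) series file.

    Returns ``(Y, names, tr)`` with ``Y`` of shape (N, T).  The TR is taken
    from the explicit argument, else from a ``<path>.json`` sidecar, else
    defaults to 1.0 with no complaint (unitless analyses are fine).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ("," if "," in first else r"\s+")
    kwargs = {"float_precision": "round_trip"} if sep != r"\s+" else {"engine": "python"}
    try:
        frame = pd.read_csv(path, sep=sep, **kwargs)
    except Exception as exc:  # noqa: BLE001 - surface parser errors uniformly
        raise ValueError(f"{path}: cannot parse series file ({exc})") from exc
    frame = frame.apply(pd.to_numeric, errors="coerce")
    _validate_numeric(frame, path)
    if tr is None:
        sidecar = path.with_name(path.name + ".json")
        if sidecar.exists():
            tr = json.loads(sidecar.read_text()).get("tr")
    return frame.to_numpy().T, list(frame.columns), float(tr) if tr else 1.0


def save_timeseries(Y: np.ndarray, path, names=None, tr: float | None = None, meta: dict | None = None):
    """Write an (N, T) series as T rows x N columns, with optional JSON sidecar."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    if names is None:
        names = [f"region_{i}" for i in range(n)]
    frame = pd.DataFrame(Y.T, columns=list(names))
    path = Path(path)
    # default float formatting is shortest round-trip representation
    frame.to_csv(path, sep=_SEP, index=False)
    if tr is not None or meta:
        sidecar = {"tr": tr, **(meta or {})}
        path.with_name(path.name + ".json").write_text(json.dumps(sidecar, indent=2))


def save_connectivity(C: np.ndarray, path, names=None):
    """Write a square connectivity matrix with region names on both axes."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("connectivity matrix must be square")
    n = C.shape[0]
    if names is None:
        names = [f"region_{i}" for i in range(n)]
    frame = pd.DataFrame(C, index=list(names), columns=list(names))
    frame.to_csv(Path(path), sep=_SEP)


def load_connectivity(path):
    frame = pd.read_csv(Path(path), sep=_SEP, index_col=0, float_precision="round_trip")
    frame = frame.apply(pd.to_numeric, errors="coerce")
    _validate_numeric(frame, path)
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"{path}: connectivity matrix must be square")
    return frame.to_numpy(), list(frame.columns)


def save_hrf(kernel: HRFKernel, path):
    """Two-column text: time_s, amplitude."""
    data = np.column_stack([kernel.times, kernel.samples])
    np.savetxt(Path(path), data, fmt="%.17g", delimiter=_SEP, header="time_s\tamplitude")


def load_hrf(path) -> HRFKernel:
    data = np.loadtxt(Path(path), delimiter=_SEP)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, amplitude)")
    t, h = data[:, 0], data[:, 1]
    dt = float(np.median(np.diff(t)))
    ipeak = int(np.argmax(h))
    imin = ipeak + int(np.argmin(h[ipeak:]))
    return HRFKernel(samples=h, dt=dt, peak_time=float(t[ipeak]), undershoot_time=float(t[imin]))


def save_edge_list(edges, path):
    """Ordered (source, target) pairs as two-column text."""
    with open(Path(path), "w") as fh:
        fh.write("source\ttarget\n")
        for src, tgt in sorted(edges):
            fh.write(f"{src}\t{tgt}\n")


def load_edge_list(path) -> set[tuple[int, int]]:
    frame = pd.read_csv(Path(path), sep=_SEP)
    return {(int(r.source), int(r.target)) for r in frame.itertuples()}


@dataclass
class RunManifest:
    """Everything needed to re-execute a CLI run bit-for-bit."""

    command: str
    settings: dict
    seed: int | None = None
    tool_version: str = ""
    python_version: str = field(default_factory=lambda: sys.version.split()[0])
    platform: str = field(default_factory=platform.platform)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    diagnostics: dict = field(default_factory=dict)


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2, default=str))
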