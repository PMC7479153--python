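"""File I/O: multi-page TIFF stacks with JSON sidecars, CSV traces, results.

A stack is stored frame-major as a multi-page TIFF; the scan timing
metadata that correlation analysis needs (dwell, line time, pixel size,
frame interval) travels in a ``<name>.json`` sidecar.  Reading refuses to
invent timing: if neither a sidecar nor an explicit :class:`ScanProtocol`
is available, that is an error, never a silent default.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

from .containers import ImageStack, IntensityTrace, ScanProtocol
from .errors import FormatError

__all__ = [
    "read_stack",
    "write_stack",
    "read_trace",
    "write_trace",
    "ResultRecord",
    "write_results",
]

_VERSION = "0.1.0"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: ImageStack, path) -> Path:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar.

    The array dtype is preserved exactly so a read-back is bit-identical.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    sidecar = _sidecar_path(path)
    with open(sidecar, "w") as fh:
        json.dump({"scan": stack.scan.to_dict(), "meta": stack.meta}, fh, indent=1)
    return path


def read_stack(path, scan: Optional[ScanProtocol] = None) -> ImageStack:
    """Read a multi-page TIFF stack and its scan metadata.

    Metadata comes from the JSON sidecar written by :func:`write_stack`,
    or from an explicit ``scan`` argument.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        raise FormatError(f"{path} holds a single frame; a stack needs >= 2")
    if data.ndim != 3:
        raise FormatError(f"{path}: expected frame x row x column data, got shape {data.shape}")
    meta: dict = {}
    if scan is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(
                f"no scan metadata for {path}: provide the JSON sidecar or an "
                "explicit ScanProtocol"
            )
        with open(sidecar) as fh:
            payload = json.load(fh)
        scan = ScanProtocol.from_dict(payload["scan"])
        meta = payload.get("meta", {})
    if data.shape[0] != scan.n_frames:
        scan = ScanProtocol.from_dict({**scan.to_dict(), "n_frames": data.shape[0]})
    return ImageStack(data, scan=scan, meta=meta)


def write_trace(trace: IntensityTrace, path) -> Path:
    """Write a trace as two-column CSV (time_s, intensity)."""
    path = Path(path)
    arr = np.column_stack([trace.times, trace.values])
    header = f"time_s,intensity\n# dwell_time={trace.dwell_time!r}"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
    return path


def read_trace(path) -> IntensityTrace:
    """Read a two-column CSV trace written by :func:`write_trace`."""
    path = Path(path)
    dwell = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# dwell_time="):
                dwell = float(line.split("=", 1)[1])
                break
    arr = np.loadtxt(path, delimiter=",", skiprows=2 if dwell is not None else 1)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns (time_s, intensity)")
    if dwell is None:
        if arr.shape[0] < 2:
            raise FormatError(f"{path}: cannot infer dwell time from one sample")
        dwell = float(arr[1, 0] - arr[0, 0])
    return IntensityTrace(arr[:, 1], dwell_time=dwell)


@dataclass
class ResultRecord:
    """One analysis stage's parameter estimates plus provenance."""

    stage: str
    estimates: dict
    uncertainties: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "estimates": _jsonable(self.estimates),
            "uncertainties": _jsonable(self.uncertainties),
            "diagnostics": _jsonable(self.diagnostics),
            "provenance": _jsonable(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResultRecord":
        return cls(
            stage=d["stage"],
            estimates=d.get("estimates", {}),
            uncertainties=d.get("uncertainties", {}),
            diagnostics=d.get("diagnostics", {}),
            provenance=d.get("provenance", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)


def input_hash(path) -> str:
    """Short SHA-256 of an input file, for provenance records."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


def write_results(records: Sequence[ResultRecord], directory) -> dict:
    """Write a JSON summary and per-stage CSV tables.

    FCS records produce rows (D_1, D_2, fraction_1, fraction_2) and RICS
    records rows (D, C, N), matching how such results are tabulated.
    Returns the mapping of written file paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summary = directory / "results.json"
    with open(summary, "w") as fh:
        json.dump([r.to_dict() for r in records], fh, indent=1)
    written = {"summary": str(summary)}
    fcs_rows, rics_rows = [], []
    for r in records:
        est = r.estimates
        if r.stage == "fcs" and "D" in est:
            ds = list(est["D"]) + [""]
            fr = list(est.get("fractions", [])) + [""]
            fcs_rows.append([ds[0], ds[1], fr[0], fr[1], est.get("N", "")])
        elif r.stage == "rics":
            rics_rows.append(
                [est.get("D", ""), est.get("concentration_nM", ""), est.get("N", "")]
            )
    if fcs_rows:
        p = directory / "fcs_table.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["D_1_um2_s", "D_2_um2_s", "fraction_1", "fraction_2", "N"])
            w.writerows(fcs_rows)
        written["fcs_table"] = str(p)
    if rics_rows:
        p = directory / "rics_table.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["D_um2_s", "C_nM", "N"])
            w.writerows(rics_rows)
        written["rics_table"] = str(p)
    return written
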