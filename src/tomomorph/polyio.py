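"""Fibril polyline I/O: CSV and legacy-ASCII VTK polydata dialects.

CSV dialect: mandatory header ``fibril_id,x_nm,y_nm,z_nm``, rows ordered
along each fibril.  VTK dialect: ``DATASET POLYDATA`` with a ``POINTS``
block and one ``LINES`` cell per fibril.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .scene import DEFAULT_MIN_FIBRIL_LENGTH, Fibril, filter_fibrils

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["fibril_id", "x_nm", "y_nm", "z_nm"]


def read_fibrils(
    path: str | Path,
    min_length: float = DEFAULT_MIN_FIBRIL_LENGTH,
    radius: float = 5.0,
) -> list[Fibril]:
    """Read fibril polylines from CSV or legacy VTK polydata.

    Fibrils shorter than ``min_length`` nm are dropped (logged).
    """
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        fibrils = _read_vtk(path, radius)
    else:
        fibrils = _read_csv(path, radius)
    return filter_fibrils(fibrils, min_length)


def _read_csv(path: Path, radius: float) -> list[Fibril]:
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; header must be "
                          f"{','.join(CSV_COLUMNS)}")
    fibrils = []
    for fid, group in table.groupby("fibril_id", sort=False):
        pts = group[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=np.float64)
        _check_ordered(pts, str(fid))
        fibrils.append(Fibril(points=pts, id=str(fid), radius=radius))
    return fibrils


def _check_ordered(pts: np.ndarray, fid: str) -> None:
    if len(pts) < 2:
        raise ValidationError(f"fibril {fid!r}: fewer than 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValidationError(f"fibril {fid!r}: duplicate consecutive points")


def write_fibrils_csv(path: str | Path, fibrils: list[Fibril]) -> None:
    rows = []
    for f in fibrils:
        for x, y, z in f.points:
            rows.append((f.id, x, y, z))
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def _read_vtk(path: Path, radius: float) -> list[Fibril]:
    tokens, meta = _tokenize_vtk(path)
    if meta.get("dataset") != "POLYDATA":
        raise FormatError(f"{path}: expected DATASET POLYDATA")
    points = meta["points"]
    fibrils = []
    for n, cell in enumerate(meta["lines"]):
        pts = points[cell]
        fid = f"fibril_{n}"
        _check_ordered(pts, fid)
        fibrils.append(Fibril(points=pts, id=fid, radius=radius))
    return fibrils


def _tokenize_vtk(path: Path) -> tuple[list[str], dict]:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise FormatError(f"{path}: not a legacy VTK file")
    if len(lines) < 3 or lines[2].strip().upper() != "ASCII":
        raise FormatError(f"{path}: only ASCII legacy VTK is supported")
    meta: dict = {"lines": []}
    i = 3
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "DATASET":
            meta["dataset"] = parts[1].upper()
            i += 1
        elif key == "POINTS":
            n = int(parts[1])
            vals: list[float] = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            meta["points"] = np.array(vals, dtype=np.float64).reshape(n, 3)
        elif key == "LINES":
            ncells = int(parts[1])
            i += 1
            flat: list[int] = []
            total = int(parts[2])
            while len(flat) < total:
                flat.extend(int(v) for v in lines[i].split())
                i += 1
            pos = 0
            for _ in range(ncells):
                npts = flat[pos]
                meta["lines"].append(np.array(flat[pos + 1 : pos + 1 + npts]))
                pos += 1 + npts
        else:
            i += 1
    if "points" not in meta:
        raise FormatError(f"{path}: no POINTS block")
    return lines, meta


def write_fibrils_vtk(path: str | Path, fibrils: list[Fibril]) -> None:
    """Write polylines as legacy-ASCII VTK polydata (one cell each)."""
    n_points = sum(len(f.points) for f in fibrils)
    out = [
        "# vtk DataFile Version 3.0",
        "fibril polylines (nm)",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n_points} double",
    ]
    for f in fibrils:
        for x, y, z in f.points:
            out.append(f"{x:.9g} {y:.9g} {z:.9g}")
    size = sum(len(f.points) + 1 for f in fibrils)
    out.append(f"LINES {len(fibrils)} {size}")
    offset = 0
    for f in fibrils:
        ids = " ".join(str(offset + i) for i in range(len(f.points)))
        out.append(f"{len(f.points)} {ids}")
        offset += len(f.points)
    Path(path).write_text("\n".join(out) + "\n")
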