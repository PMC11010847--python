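"""Point-cloud file I/O.

The pipeline's universal currency is the :class:`PointCloud`: an N x 3 array
of coordinates in meters, optionally paired with per-point 8-bit RGB colors.
This module is the only place that touches on-disk formats: PLY for clouds
(the format depth-camera toolchains export) and CSV for body-measurement
tables.

Only the ``ascii`` and ``binary_little_endian`` PLY dialects are supported;
big-endian files are rejected with a clear error rather than silently
misread. Color properties must be named ``red``/``green``/``blue`` (uchar) —
the convention used by RealSense and CloudCompare exports.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "PointCloud",
    "PLYFormatError",
    "read_ply",
    "write_ply",
    "write_measurements",
    "read_measurements",
]


class PLYFormatError(ValueError):
    """Raised when a PLY file cannot be interpreted as a point cloud."""


# PLY scalar type names -> numpy dtypes (little-endian where sized)
_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "<i2", "int16": "<i2",
    "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4",
    "uint": "<u4", "uint32": "<u4",
    "float": "<f4", "float32": "<f4",
    "double": "<f8", "float64": "<f8",
}


@dataclass
class PointCloud:
    """A 3D point set in meters with optional per-point RGB color.

    Parameters
    ----------
    points : (N, 3) float array
        Coordinates in meters, columns (x, y, z). Must be finite.
    colors : (N, 3) int array, optional
        8-bit RGB values in [0, 255], one row per point.
    source_id : str
        Free-text provenance label carried through the pipeline.
    """

    points: np.ndarray
    colors: Optional[np.ndarray] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        if self.colors is not None:
            col = np.asarray(self.colors)
            if col.size == 0 and len(pts) == 0:
                col = col.reshape(0, 3)
            if col.shape != (len(pts), 3):
                raise ValueError(
                    f"colors must be ({len(pts)}, 3), got {col.shape}"
                )
            if col.size and (col.min() < 0 or col.max() > 255):
                raise ValueError("color values must lie in [0, 255]")
            self.colors = col.astype(np.int64)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_colors(self) -> bool:
        return self.colors is not None

    def select(self, index: np.ndarray, source_id: Optional[str] = None) -> "PointCloud":
        """Return the sub-cloud at ``index`` (mask or integer index)."""
        return PointCloud(
            self.points[index],
            None if self.colors is None else self.colors[index],
            self.source_id if source_id is None else source_id,
        )


def _parse_header(fh) -> tuple[str, list[tuple[str, int, list[tuple[str, str]]]]]:
    """Parse a PLY header from a binary file handle.

    Returns (format_name, elements) where each element is
    (name, count, [(property_name, ply_type), ...]).
    List properties are recorded with type ``"list"``.
    """
    magic = fh.readline().strip()
    if magic != b"ply":
        raise PLYFormatError("not a PLY file (missing 'ply' magic)")
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    while True:
        raw = fh.readline()
        if not raw:
            raise PLYFormatError("unexpected end of file in PLY header")
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("comment") or line.startswith("obj_info"):
            continue
        if line == "end_header":
            break
        parts = line.split()
        if parts[0] == "format":
            fmt = parts[1]
            if fmt == "binary_big_endian":
                raise PLYFormatError(
                    "binary_big_endian PLY is not supported; re-export as "
                    "ascii or binary_little_endian"
                )
            if fmt not in ("ascii", "binary_little_endian"):
                raise PLYFormatError(f"unknown PLY format {fmt!r}")
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property":
            if not elements:
                raise PLYFormatError("property declared before any element")
            if parts[1] == "list":
                elements[-1][2].append((parts[-1], "list"))
            else:
                elements[-1][2].append((parts[2], parts[1]))
    if fmt is None:
        raise PLYFormatError("PLY header has no 'format' line")
    return fmt, elements


def read_ply(path) -> PointCloud:
    """Read a PLY point cloud (ascii or binary little-endian).

    The vertex element must carry ``x``, ``y``, ``z`` properties; colors are
    populated iff all of ``red``, ``green``, ``blue`` are present. Point
    order is preserved as stored.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, elements = _parse_header(fh)
        names = [e[0] for e in elements]
        if "vertex" not in names:
            raise PLYFormatError("PLY file has no 'vertex' element")
        vi = names.index("vertex")
        if vi != 0:
            # vertices must come first: skipping unknown leading elements
            # (possibly with list properties) is not supported
            raise PLYFormatError("'vertex' must be the first PLY element")
        _, n, props = elements[vi]
        prop_names = [p for p, _ in props]
        for req in ("x", "y", "z"):
            if req not in prop_names:
                raise PLYFormatError(f"vertex element missing property {req!r}")
        if any(t == "list" for _, t in props):
            raise PLYFormatError("list properties on vertex element unsupported")
        dtype = np.dtype([(p, _PLY_DTYPES[t]) for p, t in props])
        if fmt == "ascii":
            rows = []
            for _ in range(n):
                line = fh.readline().decode("ascii")
                if not line.strip():
                    raise PLYFormatError("fewer vertex lines than declared")
                rows.append(tuple(line.split()[: len(props)]))
            data = np.array(rows, dtype=dtype) if n else np.empty(0, dtype=dtype)
        else:
            buf = fh.read(dtype.itemsize * n)
            if len(buf) < dtype.itemsize * n:
                raise PLYFormatError("fewer vertex bytes than declared")
            data = np.frombuffer(buf, dtype=dtype, count=n)
    pts = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    if n == 0:
        pts = np.empty((0, 3))
    colors = None
    if all(c in prop_names for c in ("red", "green", "blue")):
        colors = np.column_stack(
            [data["red"], data["green"], data["blue"]]
        ).astype(np.int64)
        if n == 0:
            colors = np.empty((0, 3), dtype=np.int64)
    return PointCloud(pts, colors, source_id=str(path))


def write_ply(cloud: PointCloud, path, encoding: str = "binary_little_endian"):
    """Write ``cloud`` to ``path`` as PLY.

    Coordinates are stored as float32 (sub-micrometer precision at room
    scale), colors as uchar. ``read_ply(write_ply(c))`` preserves N, the
    coordinates to 1e-6 m, and colors exactly.
    """
    if encoding not in ("ascii", "binary_little_endian"):
        raise ValueError(f"unsupported encoding {encoding!r}")
    path = Path(path)
    n = len(cloud)
    header = ["ply", f"format {encoding} 1.0", f"element vertex {n}"]
    header += [f"property float {ax}" for ax in "xyz"]
    if cloud.has_colors:
        header += [f"property uchar {c}" for c in ("red", "green", "blue")]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if encoding == "ascii":
            for i in range(n):
                x, y, z = cloud.points[i]
                line = f"{x:.6f} {y:.6f} {z:.6f}"
                if cloud.has_colors:
                    r, g, b = cloud.colors[i]
                    line += f" {r:d} {g:d} {b:d}"
                fh.write((line + "\n").encode("ascii"))
        else:
            fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
            if cloud.has_colors:
                fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
            rec = np.empty(n, dtype=np.dtype(fields))
            for j, ax in enumerate("xyz"):
                rec[ax] = cloud.points[:, j]
            if cloud.has_colors:
                for j, c in enumerate(("red", "green", "blue")):
                    rec[c] = cloud.colors[:, j]
            fh.write(rec.tobytes())
    return path


_CSV_HEADER = ("id", "shoulder_m", "abdomen_m", "hip_m", "weight_kg")


def write_measurements(rows: Iterable[Sequence], path):
    """Write per-animal body measurements to CSV.

    Each row is ``(id, shoulder, abdomen, hip, weight)`` with widths in
    meters (written with 3 decimals) and weight in kg or None.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_HEADER)
        for rid, sh, ab, hip, wt in rows:
            w.writerow([
                rid,
                f"{sh:.3f}", f"{ab:.3f}", f"{hip:.3f}",
                "" if wt is None else f"{wt:.3f}",
            ])
    return path


def read_measurements(path) -> list[tuple]:
    """Parse a CSV written by :func:`write_measurements`."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != _CSV_HEADER:
            raise ValueError(f"unexpected measurement CSV header: {header}")
        for rid, sh, ab, hip, wt in reader:
            out.append((rid, float(sh), float(ab), float(hip),
                        None if wt == "" else float(wt)))
    return out
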