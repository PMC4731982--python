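"""File formats used by the TLS canopy pipeline.

Scans arrive as whitespace-delimited ASCII xyz files (one point per line,
coordinates in meters); sphere-target centers arrive as small text files with
one record per line.  A versioned binary cache mirrors the ascii clouds for
fast re-reading.  All coordinates are meters at the I/O boundary.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScanPointCloud",
    "SphereObservationSet",
    "read_xyz",
    "write_xyz",
    "cache_binary",
    "load_binary",
    "read_sphere_file",
    "write_deviation_csv",
]

#: Frames a cloud can be expressed in.  "scanner" is the instrument-local frame
#: of a single scan; "fixed" is the season-constant frame defined by the sphere
#: targets.  The frame is always declared, never inferred.
FRAMES = ("scanner", "fixed")

_XYZ_DECIMALS = 6  # write precision: 1 µm, far below the 2 mm scanner accuracy


@dataclass
class ScanPointCloud:
    """A 3D scan point cloud with scan metadata.

    Parameters
    ----------
    points : (n, 3) float array
        Point coordinates in meters.
    scan_id : str
        Identifier of the scan (typically derived from the file name).
    frame : {"scanner", "fixed"}
        Coordinate frame the points are expressed in.
    timestamp : datetime, optional
        Acquisition time, if known.
    """

    points: np.ndarray
    scan_id: str = ""
    frame: str = "scanner"
    timestamp: datetime | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got shape {pts.shape}")
        if not np.isfinite(pts).all():
            raise ValueError("point coordinates must be finite")
        if self.frame not in FRAMES:
            raise ValueError(f"frame must be one of {FRAMES}, got {self.frame!r}")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray, frame: str | None = None) -> "ScanPointCloud":
        return replace(self, points=points, frame=frame or self.frame)

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


@dataclass
class SphereObservationSet:
    """Observed sphere-target centers, possibly from several scans.

    Backed by a DataFrame with columns ``sphere_id, x, y, z, scan_id``.
    The pair (sphere_id, scan_id) is unique.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sphere_id", "x", "y", "z", "scan_id"]))

    def __post_init__(self) -> None:
        required = ["sphere_id", "x", "y", "z", "scan_id"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"sphere table missing columns {missing}")
        dup = self.table.duplicated(subset=["sphere_id", "scan_id"])
        if dup.any():
            bad = self.table.loc[dup, ["sphere_id", "scan_id"]].iloc[0]
            raise ValueError(
                f"duplicate sphere observation: sphere {bad.sphere_id!r} "
                f"in scan {bad.scan_id!r}")
        if not np.isfinite(self.table[["x", "y", "z"]].to_numpy(dtype=float)).all():
            raise ValueError("sphere centers must be finite")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, Sequence[float], str]]
                     ) -> "SphereObservationSet":
        rows = [{"sphere_id": sid, "x": c[0], "y": c[1], "z": c[2], "scan_id": scan}
                for sid, c, scan in records]
        return cls(pd.DataFrame(rows, columns=["sphere_id", "x", "y", "z", "scan_id"]))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def scan_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["scan_id"]))

    def for_scan(self, scan_id: str) -> "SphereObservationSet":
        sub = self.table[self.table["scan_id"] == scan_id].reset_index(drop=True)
        return SphereObservationSet(sub)

    def centers_by_id(self) -> dict[str, np.ndarray]:
        """sphere_id -> (3,) center; raises if a sphere appears more than once."""
        out: dict[str, np.ndarray] = {}
        for row in self.table.itertuples():
            if row.sphere_id in out:
                raise ValueError(
                    f"sphere {row.sphere_id!r} appears in several scans; "
                    "select one scan first")
            out[row.sphere_id] = np.array([row.x, row.y, row.z], dtype=float)
        return out


# ---------------------------------------------------------------------------
# ascii xyz
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path, column_spec: tuple[int, int, int] = (1, 2, 3),
             scan_id: str | None = None) -> ScanPointCloud:
    """Read a whitespace-delimited ascii xyz file.

    ``column_spec`` gives the 1-based columns holding x, y and z; extra columns
    (intensity, color, ...) are ignored.  Lines starting with ``#`` and blank
    lines are skipped.  A line whose x/y/z fields are not numeric raises a
    ``ValueError`` naming the 1-based line number.
    """
    path = Path(path)
    cols = tuple(c - 1 for c in column_spec)
    if min(cols) < 0:
        raise ValueError("column_spec is 1-based; columns must be >= 1")
    pts: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            try:
                pts.append(tuple(float(fields[c]) for c in cols))
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: cannot parse x/y/z on line {lineno}: {stripped!r}"
                ) from exc
    arr = np.array(pts, dtype=np.float64).reshape(len(pts), 3)
    return ScanPointCloud(arr, scan_id=scan_id if scan_id is not None else path.stem,
                          frame="scanner")


def write_xyz(cloud: ScanPointCloud, path: str | Path) -> Path:
    """Write a cloud as ascii xyz with 6 decimal places (µm precision)."""
    path = Path(path)
    np.savetxt(path, cloud.points, fmt=f"%.{_XYZ_DECIMALS}f", delimiter=" ")
    return path


# ---------------------------------------------------------------------------
# binary cache
# ---------------------------------------------------------------------------

_MAGIC = b"TLSC"
_CACHE_VERSION = 1


def cache_binary(cloud: ScanPointCloud, path: str | Path) -> Path:
    """Write a lossless, versioned binary cache of a cloud.

    Layout: magic ``TLSC``, uint16 version, uint32 metadata length, UTF-8 JSON
    metadata, uint64 point count, then the contiguous float64 xyz block.
    """
    path = Path(path)
    meta = {
        "scan_id": cloud.scan_id,
        "frame": cloud.frame,
        "timestamp": cloud.timestamp.isoformat() if cloud.timestamp else None,
    }
    meta_bytes = json.dumps(meta).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<HI", _CACHE_VERSION, len(meta_bytes)))
        fh.write(meta_bytes)
        fh.write(struct.pack("<Q", cloud.n_points))
        fh.write(np.ascontiguousarray(cloud.points, dtype="<f8").tobytes())
    return path


def load_binary(path: str | Path) -> ScanPointCloud:
    """Load a binary cache; truncation or version mismatch raises, never misreads."""
    path = Path(path)
    data = Path(path).read_bytes()
    if data[:4] != _MAGIC:
        raise ValueError(f"{path}: not a point-cloud cache (bad magic)")
    try:
        version, meta_len = struct.unpack_from("<HI", data, 4)
    except struct.error as exc:
        raise ValueError(f"{path}: truncated cache header") from exc
    if version != _CACHE_VERSION:
        raise ValueError(
            f"{path}: cache version {version} not supported (expected {_CACHE_VERSION})")
    off = 10
    meta = json.loads(data[off:off + meta_len].decode())
    off += meta_len
    try:
        (n,) = struct.unpack_from("<Q", data, off)
    except struct.error as exc:
        raise ValueError(f"{path}: truncated cache") from exc
    off += 8
    expected = n * 3 * 8
    block = data[off:off + expected]
    if len(block) != expected:
        raise ValueError(
            f"{path}: truncated cache: expected {expected} coordinate bytes, "
            f"found {len(block)}")
    pts = np.frombuffer(block, dtype="<f8").reshape(n, 3).copy()
    ts = datetime.fromisoformat(meta["timestamp"]) if meta.get("timestamp") else None
    return ScanPointCloud(pts, scan_id=meta.get("scan_id", ""),
                          frame=meta.get("frame", "scanner"), timestamp=ts)


# ---------------------------------------------------------------------------
# sphere files and reports
# ---------------------------------------------------------------------------

def read_sphere_file(path: str | Path) -> SphereObservationSet:
    """Read sphere centers: one ``id x y z [scan_id]`` record per line.

    Missing scan_id defaults to the file stem.  ``#`` comment lines are
    skipped.  A duplicate (sphere_id, scan_id) pair raises.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'id x y z [scan_id]', "
                    f"got {stripped!r}")
            try:
                center = [float(v) for v in fields[1:4]]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric center in {stripped!r}"
                ) from exc
            scan = fields[4] if len(fields) > 4 else path.stem
            rows.append({"sphere_id": fields[0], "x": center[0], "y": center[1],
                         "z": center[2], "scan_id": scan})
    return SphereObservationSet(
        pd.DataFrame(rows, columns=["sphere_id", "x", "y", "z", "scan_id"]))


def write_deviation_csv(report: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-observation deviation report.

    Expects columns sphere_id, scan_id, dx, dy, dz, euclidean_deviation_m.
    """
    required = ["sphere_id", "scan_id", "dx", "dy", "dz", "euclidean_deviation_m"]
    missing = [c for c in required if c not in report.columns]
    if missing:
        raise ValueError(f"deviation report missing columns {missing}")
    path = Path(path)
    report.to_csv(path, index=False)
    return path
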