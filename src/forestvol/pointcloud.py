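"""Point-cloud container and LAS 1.2 / CSV readers and writers.

Two interchangeable on-disk dialects are supported:

* **LAS 1.2, point format 0** — the airborne-survey exchange format; the
  ASPRS classification byte encodes ground returns (class 2) versus
  vegetation (class 5). Coordinates are stored as scaled 32-bit integers,
  so a scale of 0.001 m preserves millimetre precision.
* **CSV** with the mandatory header ``x,y,z,intensity,is_ground``.

The writer/reader pair round-trips coordinates to the LAS scale (1 mm) and
intensity to the nearest integer.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PointCloud", "read_las", "write_las", "read_cloud_csv", "write_cloud_csv"]

_GROUND_CLASS = 2
_VEG_CLASS = 5
_HEADER_SIZE = 227  # LAS 1.2
_POINT_SIZE = 20    # point data record format 0


@dataclass
class PointCloud:
    """Per-plot point set in projected metres; z may be absolute or height above ground."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    intensity: np.ndarray
    is_ground: np.ndarray
    plot_id: str = ""
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.is_ground = np.asarray(self.is_ground, dtype=bool)
        n = len(self.x)
        if not (len(self.y) == len(self.z) == len(self.intensity) == len(self.is_ground) == n):
            raise ValueError("all point attribute arrays must share one length")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def canopy(self) -> "PointCloud":
        m = ~self.is_ground
        return PointCloud(self.x[m], self.y[m], self.z[m], self.intensity[m],
                          self.is_ground[m], self.plot_id, self.normalized)


def write_las(cloud: PointCloud, path: str | Path, scale: float = 0.001) -> None:
    """Write a minimal LAS 1.2 (point format 0) file."""
    path = Path(path)
    n = len(cloud)
    if n == 0:
        raise ValueError("refusing to write an empty LAS file")
    offs = (float(cloud.x.min()), float(cloud.y.min()), float(cloud.z.min()))
    xi = np.round((cloud.x - offs[0]) / scale).astype("<i4")
    yi = np.round((cloud.y - offs[1]) / scale).astype("<i4")
    zi = np.round((cloud.z - offs[2]) / scale).astype("<i4")
    inten = np.clip(np.round(cloud.intensity), 0, 65535).astype("<u2")
    cls = np.where(cloud.is_ground, _GROUND_CLASS, _VEG_CLASS).astype("u1")

    rec = np.zeros(n, dtype=[("x", "<i4"), ("y", "<i4"), ("z", "<i4"),
                             ("intensity", "<u2"), ("flags", "u1"),
                             ("classification", "u1"), ("scan_angle", "i1"),
                             ("user_data", "u1"), ("point_source", "<u2")])
    rec["x"], rec["y"], rec["z"] = xi, yi, zi
    rec["intensity"] = inten
    rec["flags"] = 0b00001001  # single return, first of one
    rec["classification"] = cls

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4s", header, 0, b"LASF")
    struct.pack_into("<BB", header, 24, 1, 2)                    # version 1.2
    struct.pack_into("<32s", header, 26, b"forestvol")           # system id
    struct.pack_into("<32s", header, 58, b"forestvol synthetic")  # software
    struct.pack_into("<HH", header, 90, 1, 2021)                 # day/year
    struct.pack_into("<H", header, 94, _HEADER_SIZE)
    struct.pack_into("<I", header, 96, _HEADER_SIZE)             # point data offset
    struct.pack_into("<I", header, 100, 0)                       # no VLRs
    struct.pack_into("<B", header, 104, 0)                       # point format 0
    struct.pack_into("<H", header, 105, _POINT_SIZE)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<5I", header, 111, n, 0, 0, 0, 0)          # returns by pulse
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *offs)
    struct.pack_into("<6d", header, 179,
                     float(cloud.x.max()), float(cloud.x.min()),
                     float(cloud.y.max()), float(cloud.y.min()),
                     float(cloud.z.max()), float(cloud.z.min()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


def read_las(path: str | Path, plot_id: str = "") -> PointCloud:
    path = Path(path)
    raw = path.read_bytes()
    if raw[:4] != b"LASF":
        raise ValueError(f"{path}: not a LAS file (bad signature)")
    major, minor = struct.unpack_from("<BB", raw, 24)
    if (major, minor) != (1, 2):
        raise ValueError(f"{path}: unsupported LAS version {major}.{minor}")
    offset = struct.unpack_from("<I", raw, 96)[0]
    fmt = struct.unpack_from("<B", raw, 104)[0]
    if fmt not in (0, 1):
        raise ValueError(f"{path}: unsupported point format {fmt}")
    rec_len = struct.unpack_from("<H", raw, 105)[0]
    n = struct.unpack_from("<I", raw, 107)[0]
    sx, sy, sz = struct.unpack_from("<3d", raw, 131)
    ox, oy, oz = struct.unpack_from("<3d", raw, 155)
    body = np.frombuffer(raw, dtype=np.uint8, count=n * rec_len, offset=offset)
    body = body.reshape(n, rec_len)
    xi = body[:, 0:4].copy().view("<i4").ravel()
    yi = body[:, 4:8].copy().view("<i4").ravel()
    zi = body[:, 8:12].copy().view("<i4").ravel()
    inten = body[:, 12:14].copy().view("<u2").ravel()
    cls = body[:, 15]
    return PointCloud(x=xi * sx + ox, y=yi * sy + oy, z=zi * sz + oz,
                      intensity=inten.astype(float),
                      is_ground=(cls & 0x1F) == _GROUND_CLASS,
                      plot_id=plot_id or path.stem)


_CSV_COLUMNS = ["x", "y", "z", "intensity", "is_ground"]


def write_cloud_csv(cloud: PointCloud, path: str | Path) -> None:
    df = pd.DataFrame({"x": cloud.x, "y": cloud.y, "z": cloud.z,
                       "intensity": cloud.intensity,
                       "is_ground": cloud.is_ground.astype(int)})
    df.to_csv(path, index=False)


def read_cloud_csv(path: str | Path, plot_id: str = "") -> PointCloud:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: point CSV is missing columns {missing}")
    return PointCloud(x=df["x"].to_numpy(), y=df["y"].to_numpy(), z=df["z"].to_numpy(),
                      intensity=df["intensity"].to_numpy(),
                      is_ground=df["is_ground"].to_numpy().astype(bool),
                      plot_id=plot_id or Path(path).stem)
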