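"""In-memory containers for stacks, traces and trajectories.

Conventions
-----------
* Voxel stacks are indexed ``[z, y, x]`` (tifffile order); ``voxel_size`` is
  ``(dz, dy, dx)`` in μm and a voxel's world position is its **center**:
  ``origin + index * voxel_size``.
* Traces carry their sample rate; time is implicit (``t = i / rate``).
* All physical units are μm, s, mV, pA unless a field says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import InputError


@dataclass
class VoxelStack:
    """A 3D intensity (or binary) grid with voxel size and world origin."""

    data: np.ndarray                      # [z, y, x]
    voxel_size: tuple[float, float, float]  # (dz, dy, dx) μm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # world μm of voxel (0,0,0) center

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InputError("VoxelStack data must be 3D (z, y, x)")
        vs = tuple(float(v) for v in np.broadcast_to(self.voxel_size, (3,)))
        if any(v <= 0 for v in vs):
            raise InputError("voxel_size must be positive")
        self.voxel_size = vs
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World (x, y, z) μm coordinates of voxel centers.

        With ``mask`` given, only centers of True voxels are returned.
        """
        if mask is None:
            idx = np.indices(self.data.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        dz, dy, dx = self.voxel_size
        oz, oy, ox = self.origin
        zyx = idx * np.array([dz, dy, dx]) + np.array([oz, oy, ox])
        return zyx[:, ::-1]  # (x, y, z)

    def save(self, path: str | Path) -> None:
        """Write TIFF plus a YAML sidecar holding voxel size and origin."""
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.data))
        sidecar = path.with_suffix(path.suffix + ".yaml")
        meta = {"voxel_size_um": list(self.voxel_size), "origin_um": list(self.origin)}
        sidecar.write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelStack":
        path = Path(path)
        data = tifffile.imread(path)
        sidecar = path.with_suffix(path.suffix + ".yaml")
        meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            data=data,
            voxel_size=tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0))),
            origin=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
        )


@dataclass
class LFPRecording:
    """Local field potential trace (mV) with its sampling rate."""

    samples: np.ndarray  # mV
    sample_rate: float   # Hz

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("LFP samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class VCTrace:
    """Voltage-clamp current trace (pA) with its sampling rate."""

    samples: np.ndarray  # pA
    sample_rate: float   # Hz

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise InputError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class Trajectory:
    """Animal position per video frame, in arena units.

    ``calibration`` converts arena units to cm (cm per unit).
    """

    t: np.ndarray            # s
    x: np.ndarray            # arena units
    y: np.ndarray            # arena units
    calibration: float = 1.0  # cm per arena unit

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise InputError("t, x, y must have equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise InputError("trajectory times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.t.size


def save_trace_csv(path: str | Path, trace, unit: str) -> None:
    """Trace to CSV with a units header (t_s, value columns)."""
    t = trace.times
    with open(path, "w") as fh:
        fh.write(f"t_s,value_{unit}\n")
        for ti, vi in zip(t, trace.samples):
            fh.write(f"{ti:.6g},{vi:.9g}\n")


def load_trace_csv(path: str | Path, cls=LFPRecording):
    """Read a two-column (t_s, value) CSV back into a trace container."""
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InputError("trace CSV needs at least two samples")
    dt = np.diff(arr[:, 0])
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
        raise InputError("trace CSV must be uniformly sampled")
    return cls(samples=arr[:, 1], sample_rate=1.0 / float(dt[0]))
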