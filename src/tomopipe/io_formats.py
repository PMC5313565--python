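"""Raw-scan, log and volume I/O.

Two container formats are supported for raw scans: a single HDF5 file in the
scientific data-exchange layout (datasets ``exchange/data``,
``exchange/data_white``, ``exchange/data_dark``, ``exchange/theta``; one full
frame per chunk for fast single-frame access) and a directory of single-page
TIFF files with a plain-text sidecar log. Calibration results travel in a
flat ``key=value`` text log (ScanLog); reconstructed volumes are written as
32-bit float TIFF stacks or a single HDF5 dataset.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import tifffile

from .errors import FormatError, InvalidArgument

__all__ = [
    "RawScan", "ScanLog",
    "write_dxchange", "read_dxchange", "read_frames",
    "write_tiff_dir", "read_tiff_dir",
    "write_volume", "read_volume",
]

_EXCHANGE = {
    "data": "exchange/data",
    "white": "exchange/data_white",
    "dark": "exchange/data_dark",
    "theta": "exchange/theta",
}


@dataclass
class RawScan:
    """A raw tomographic scan: projection, flat and dark frame stacks.

    Invariants: ``len(angles) == n_proj`` and all stacks share the frame
    shape ``(rows, cols)``.
    """

    projections: np.ndarray
    flats: np.ndarray
    darks: np.ndarray
    angles: np.ndarray
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections)
        self.flats = np.asarray(self.flats)
        self.darks = np.asarray(self.darks)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.projections.ndim != 3:
            raise InvalidArgument("projections must be (n_proj, rows, cols)")
        if len(self.angles) != self.n_proj:
            raise InvalidArgument(
                f"{self.n_proj} projections but {len(self.angles)} angles")
        shape = self.frame_shape
        for name, stack in (("flats", self.flats), ("darks", self.darks)):
            if stack.ndim != 3 or stack.shape[1:] != shape:
                raise InvalidArgument(
                    f"{name} frames {stack.shape[1:]} do not match "
                    f"projection frames {shape}")

    @property
    def n_proj(self) -> int:
        return self.projections.shape[0]

    @property
    def frame_shape(self):
        return self.projections.shape[1:]

    def __eq__(self, other) -> bool:
        if not isinstance(other, RawScan):
            return NotImplemented
        return (np.array_equal(self.projections, other.projections)
                and np.array_equal(self.flats, other.flats)
                and np.array_equal(self.darks, other.darks)
                and np.array_equal(self.angles, other.angles))


@dataclass
class ScanLog:
    """Calibration results + scan facts, shared between pipeline stages."""

    center: Optional[float] = None
    tilt: Optional[float] = None
    overlap: Optional[int] = None
    n_proj: Optional[int] = None
    angular_range: Optional[float] = None
    extras: Dict[str, str] = field(default_factory=dict)

    _FLOATS = ("center", "tilt", "angular_range")
    _INTS = ("overlap", "n_proj")

    def save(self, path) -> None:
        lines = []
        for name in self._FLOATS:
            v = getattr(self, name)
            if v is not None:
                lines.append(f"{name}={float(v)!r}")
        for name in self._INTS:
            v = getattr(self, name)
            if v is not None:
                lines.append(f"{name}={int(v)}")
        for k, v in self.extras.items():
            lines.append(f"{k}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "ScanLog":
        log = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = line.split("=", 1)
            key = key.strip()
            if key in cls._FLOATS:
                setattr(log, key, float(value))
            elif key in cls._INTS:
                setattr(log, key, int(value))
            else:
                log.extras[key] = value
        return log


def write_dxchange(scan: RawScan, path, compression: Optional[str] = None) -> None:
    """Write a RawScan to a single data-exchange HDF5 file.

    Frame stacks are chunked one full frame per chunk, optimized for fast
    single-frame access.
    """
    path = Path(path)
    try:
        f = h5py.File(path, "w")
    except OSError as exc:
        raise IOError(f"cannot write HDF5 file {path}: {exc}") from exc
    with f:
        rows, cols = scan.frame_shape
        for key, stack in (("data", scan.projections),
                           ("white", scan.flats),
                           ("dark", scan.darks)):
            f.create_dataset(_EXCHANGE[key], data=stack,
                             chunks=(1, rows, cols), compression=compression)
        f.create_dataset(_EXCHANGE["theta"], data=scan.angles)
        if scan.metadata:
            f["exchange"].attrs["metadata"] = json.dumps(
                scan.metadata, default=str)


def _open_dataset(f: h5py.File, key: str) -> h5py.Dataset:
    name = _EXCHANGE[key]
    if name not in f:
        raise FormatError(f"missing HDF5 dataset '{name}'")
    return f[name]


def read_dxchange(path) -> RawScan:
    """Read a full RawScan back from a data-exchange HDF5 file."""
    with h5py.File(path, "r") as f:
        meta = {}
        if "exchange" in f and "metadata" in f["exchange"].attrs:
            meta = json.loads(f["exchange"].attrs["metadata"])
        return RawScan(
            projections=_open_dataset(f, "data")[...],
            flats=_open_dataset(f, "white")[...],
            darks=_open_dataset(f, "dark")[...],
            angles=_open_dataset(f, "theta")[...],
            metadata=meta,
        )


def read_frames(path, kind: str, indices: Sequence[int]) -> np.ndarray:
    """Read selected frames (kind: data|white|dark) in request order.

    Contiguous runs of indices are fetched as block reads against the
    frame-per-chunk layout; an out-of-range index raises before any data is
    returned.
    """
    key = {"data": "data", "white": "white", "dark": "dark"}.get(kind)
    if key is None:
        raise InvalidArgument(f"kind must be data|white|dark, got {kind!r}")
    indices = list(indices)
    with h5py.File(path, "r") as f:
        ds = _open_dataset(f, key)
        n = ds.shape[0]
        for i in indices:
            if not (0 <= i < n):
                raise InvalidArgument(f"frame index {i} out of range [0, {n})")
        out = np.empty((len(indices),) + ds.shape[1:], dtype=ds.dtype)
        pos = 0
        while pos < len(indices):
            run = 1
            while (pos + run < len(indices)
                   and indices[pos + run] == indices[pos] + run):
                run += 1
            start = indices[pos]
            out[pos:pos + run] = ds[start:start + run]
            pos += run
    return out


_ROLE_PREFIX = {"proj": "projections", "flat": "flats", "dark": "darks"}


def write_tiff_dir(scan: RawScan, path) -> None:
    """Write a RawScan as a directory of single-page TIFFs + sidecar logs."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for prefix, attr in _ROLE_PREFIX.items():
        for i, frame in enumerate(getattr(scan, attr)):
            tifffile.imwrite(path / f"{prefix}_{i:05d}.tif", frame)
    np.savetxt(path / "theta.txt", scan.angles, fmt="%.17g")
    log = ScanLog(n_proj=scan.n_proj)
    log.extras.update({k: str(v) for k, v in scan.metadata.items()})
    log.save(path / "scan.log")


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(p: Path) -> int:
    m = _NUM_RE.findall(p.stem)
    if not m:
        raise FormatError(f"cannot parse a frame index from {p.name}")
    return int(m[-1])


def read_tiff_dir(path, pattern: str = "*.tif") -> RawScan:
    """Read a TIFF-directory scan; frames ordered by numeric file index."""
    path = Path(path)
    stacks = {}
    for prefix, attr in _ROLE_PREFIX.items():
        files = sorted(path.glob(f"{prefix}_{pattern}"), key=_numeric_key)
        if not files:
            raise FormatError(f"no '{prefix}_*.tif' files in {path}")
        frames = [tifffile.imread(f) for f in files]
        shape0 = frames[0].shape
        for f, fr in zip(files, frames):
            if fr.shape != shape0:
                raise FormatError(
                    f"frame {f.name} has shape {fr.shape}, expected {shape0}")
        stacks[attr] = np.stack(frames)
    theta_file = path / "theta.txt"
    if theta_file.exists():
        angles = np.atleast_1d(np.loadtxt(theta_file))
    else:
        n = stacks["projections"].shape[0]
        angles = np.linspace(0.0, 180.0, n, endpoint=False)
    meta = {}
    if (path / "scan.log").exists():
        meta = dict(ScanLog.load(path / "scan.log").extras)
    return RawScan(angles=angles, metadata=meta, **stacks)


def write_volume(slices: np.ndarray, path, format: str = "tiff-stack",
                 roi: Optional[tuple] = None) -> List[Path]:
    """Write reconstructed slices as 32-bit float files.

    ``roi`` is ``(x0, x1, y0, y1)`` in slice pixel coordinates, applied
    before writing. Returns the list of files written.
    """
    vol = np.asarray(slices, dtype=np.float32)
    if vol.ndim == 2:
        vol = vol[None]
    if roi is not None:
        x0, x1, y0, y1 = roi
        vol = vol[:, y0:y1, x0:x1]
    path = Path(path)
    if format == "tiff-stack":
        path.mkdir(parents=True, exist_ok=True)
        out = []
        for i, sl in enumerate(vol):
            p = path / f"slice_{i:05d}.tif"
            tifffile.imwrite(p, sl)
            out.append(p)
        return out
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("volume", data=vol)
        return [path]
    raise InvalidArgument(
        f"unknown volume format {format!r}; supported: tiff-stack, hdf5")


def read_volume(path, format: str = "tiff-stack") -> np.ndarray:
    """Read back a volume written by :func:`write_volume`."""
    path = Path(path)
    if format == "tiff-stack":
        files = sorted(path.glob("slice_*.tif"), key=_numeric_key)
        if not files:
            raise FormatError(f"no 'slice_*.tif' files in {path}")
        return np.stack([tifffile.imread(f) for f in files])
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            return f["volume"][...]
    raise InvalidArgument(
        f"unknown volume format {format!r}; supported: tiff-stack, hdf5")
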