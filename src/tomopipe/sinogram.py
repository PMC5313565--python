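"""Flat-/dark-field correction, sinogram assembly and the partition plan.

A sinogram holds normalized transmission (dimensionless, ~ exp(-line
integral)) for one detector row across all projection angles. The logarithm
is deliberately deferred to the reconstruction stage: phase retrieval
operates on normalized intensity, so taking -ln here would be premature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import DegenerateReference, InvalidArgument
from .io_formats import RawScan, ScanLog

__all__ = [
    "Sinogram", "PartitionPlan",
    "average_references", "normalize", "normalize_scan",
    "build_sinograms", "plan_partition",
]

#: transmission floor before any downstream logarithm (dead-pixel guard)
DEFAULT_FLOOR = 1.0e-6

#: read block size: largest whole-frame count below this many bytes
DEFAULT_BLOCK_BYTES = 64 * 1024 * 1024


@dataclass
class Sinogram:
    """(angle x detector-column) normalized transmission for one row."""

    values: np.ndarray
    row: int
    angles: np.ndarray
    center: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.values.ndim != 2:
            raise InvalidArgument("sinogram values must be 2D (angle, column)")
        if self.values.shape[0] != len(self.angles):
            raise InvalidArgument("sinogram rows must match the angle list")


@dataclass
class PartitionPlan:
    """Deterministic reader/compute split of a pool of cores."""

    n_total: int
    n_nodes: int
    reader_ranks: List[int]
    compute_ranks: List[int]
    block_size: int = 1

    @property
    def n_readers(self) -> int:
        return len(self.reader_ranks)


def average_references(flats: np.ndarray, darks: np.ndarray):
    """Pixelwise mean white (flat) and dark frames."""
    flats = np.asarray(flats, dtype=float)
    darks = np.asarray(darks, dtype=float)
    if flats.ndim != 3 or flats.shape[0] < 1:
        raise InvalidArgument("need at least one flat frame")
    if darks.ndim != 3 or darks.shape[0] < 1:
        raise InvalidArgument("need at least one dark frame")
    return flats.mean(axis=0), darks.mean(axis=0)


def normalize(frame: np.ndarray, white: np.ndarray, dark: np.ndarray,
              floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """Dark-subtract and flat-normalize one frame (or a frame stack).

    ``(frame - dark) / max(white - dark, floor)``, clipped below at
    ``floor``. Scale-invariant: a common positive factor on frame, white and
    dark cancels.
    """
    frame = np.asarray(frame, dtype=float)
    denom = np.asarray(white, dtype=float) - np.asarray(dark, dtype=float)
    if np.all(denom <= 0):
        raise DegenerateReference("white - dark is non-positive everywhere")
    denom = np.maximum(denom, floor)
    return np.clip((frame - dark) / denom, floor, None)


def normalize_scan(scan: RawScan, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """Normalized transmission stack (n_proj, rows, cols) of a raw scan."""
    if scan.flats.shape[0] < 1 or scan.darks.shape[0] < 1:
        raise DegenerateReference("scan has no flat or no dark frames")
    white, dark = average_references(scan.flats, scan.darks)
    return normalize(scan.projections, white, dark, floor=floor)


def build_sinograms(
    scan: RawScan,
    rows: Optional[Sequence[int]] = None,
    log: Optional[ScanLog] = None,
    floor: float = DEFAULT_FLOOR,
    normalized: Optional[np.ndarray] = None,
) -> List[Sinogram]:
    """Reorganize a scan into per-row sinograms.

    ``sinogram[row][p, c]`` is the normalized projection ``p`` at detector
    position ``(row, c)``. The center of rotation is attached from the scan
    log when available. Pass ``normalized`` to reuse an already-normalized
    projection stack (pure reorganization, independent of any read plan).
    """
    if normalized is None:
        normalized = normalize_scan(scan, floor=floor)
    n_rows = normalized.shape[1]
    if rows is None:
        rows = range(n_rows)
    center = log.center if log is not None else None
    out = []
    for r in rows:
        if not (0 <= r < n_rows):
            raise InvalidArgument(f"row {r} outside detector height {n_rows}")
        out.append(Sinogram(values=normalized[:, r, :].copy(), row=int(r),
                            angles=scan.angles.copy(), center=center))
    return out


def plan_partition(n_total: int, n_nodes: int,
                   target_ratio: float = 7.0,
                   frame_bytes: int = 2 * 2048 * 2048,
                   block_bytes: int = DEFAULT_BLOCK_BYTES) -> PartitionPlan:
    """Split ``n_total`` cores on ``n_nodes`` nodes into readers and workers.

    The reader count is the multiple of ``n_nodes`` closest to
    ``n_total / (target_ratio + 1)`` (compute:reader ratios around 1:6-1:8
    work well on medium clusters), floored at one reader per node, with
    readers assigned round-robin so every node carries the same number.
    Exact ties round toward more readers on multi-node systems (spreading
    the I/O load) and toward fewer on a single node.
    """
    if n_nodes < 1:
        raise InvalidArgument("n_nodes must be >= 1")
    if n_total < 2 * n_nodes:
        raise InvalidArgument(
            f"need at least 2 cores per node, got {n_total} on {n_nodes}")
    if n_total % n_nodes:
        raise InvalidArgument("n_total must be divisible by n_nodes")
    ideal = n_total / (target_ratio + 1.0)
    m = ideal / n_nodes
    frac = m - np.floor(m)
    if frac > 0.5 or (frac == 0.5 and n_nodes > 1):
        m = int(np.ceil(m))
    else:
        m = int(np.floor(m))
    n_readers = max(n_nodes, m * n_nodes)
    n_readers = min(n_readers, n_total - n_nodes)  # leave compute cores

    per_node = n_total // n_nodes
    readers_per_node = n_readers // n_nodes
    reader_ranks = []
    for node in range(n_nodes):
        base = node * per_node
        reader_ranks.extend(range(base, base + readers_per_node))
    compute_ranks = [r for r in range(n_total) if r not in set(reader_ranks)]
    block = max(1, block_bytes // max(1, frame_bytes))
    return PartitionPlan(n_total=n_total, n_nodes=n_nodes,
                         reader_ranks=reader_ranks,
                         compute_ranks=compute_ranks, block_size=block)
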