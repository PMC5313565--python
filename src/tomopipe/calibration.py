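"""Pre-pass calibration: center of rotation, axis tilt, extended-FOV overlap.

The center of rotation is found by registering the 0-degree projection
against the horizontally mirrored 180-degree projection with normalized
cross-correlation and parabolic sub-pixel refinement; a tilted axis shows up
as a linear drift of the per-row center and is compensated by rotating the
projection frames; for extended-FOV (half-acquisition) scans the same
registration yields the projection overlap used to stitch opposing
projections into a double-width 180-degree scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import EstimationFailed, InvalidArgument
from .io_formats import ScanLog

__all__ = [
    "ScanGeometry", "CenterEstimate", "TiltEstimate",
    "estimate_center", "estimate_tilt", "rotate_projections",
    "estimate_overlap", "stitch_pairs", "calibrate_scan",
]


@dataclass
class ScanGeometry:
    """Rotation-axis geometry of one scan."""

    center: float
    tilt: float = 0.0
    overlap: Optional[int] = None
    per_row_centers: Optional[List[Tuple[float, float]]] = None
    center_slope: float = 0.0  # d(center)/d(row), from the tilt fit
    center_intercept: Optional[float] = None

    def center_at_row(self, row: float) -> float:
        """Per-row center from the tilt fit (constant if no fit present)."""
        if self.center_intercept is None:
            return self.center
        return self.center_intercept + self.center_slope * row


@dataclass
class CenterEstimate:
    center: float
    shift: float
    boundary: bool  # correlation peak on the search boundary => unreliable

    def __float__(self) -> float:
        return float(self.center)


@dataclass
class TiltEstimate:
    tilt: float
    per_row_centers: List[Tuple[float, float]]
    intercept: float
    slope: float


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-size blocks."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return 0.0
    return float((a * b).sum() / denom)


def _parabolic_peak(scores: np.ndarray, idx: int) -> float:
    """Sub-sample peak position via a parabola through idx and neighbors."""
    if idx <= 0 or idx >= len(scores) - 1:
        return float(idx)
    c0, c1, c2 = scores[idx - 1], scores[idx], scores[idx + 1]
    denom = c0 - 2.0 * c1 + c2
    if denom == 0.0:
        return float(idx)
    return idx + 0.5 * (c0 - c2) / denom


def estimate_center(proj_0: np.ndarray, proj_180: np.ndarray,
                    search_halfwidth: int = 50) -> CenterEstimate:
    """Center of rotation from a 0/180-degree projection pair.

    Mirrors the 180-degree frame horizontally and scans integer shifts in
    ``[-search_halfwidth, +search_halfwidth]`` for the maximum normalized
    cross-correlation; the peak is refined to sub-pixel precision with a
    parabolic fit. If the axis sits at column c = (cols-1)/2 + d, the mirror
    is displaced by 2d, so ``center = (cols - 1) / 2 + shift / 2``.
    """
    p0 = np.atleast_2d(np.asarray(proj_0, dtype=float))
    p180 = np.atleast_2d(np.asarray(proj_180, dtype=float))
    if p0.shape != p180.shape:
        raise InvalidArgument("projection pair shapes differ")
    cols = p0.shape[1]
    mirror = p180[:, ::-1]
    hw = int(search_halfwidth)
    shifts = np.arange(-hw, hw + 1)
    scores = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        if s >= 0:
            a, b = p0[:, s:], mirror[:, :cols - s]
        else:
            a, b = p0[:, :cols + s], mirror[:, -s:]
        scores[i] = _ncc(a, b)
    best = int(np.argmax(scores))
    boundary = best in (0, len(shifts) - 1)
    refined = _parabolic_peak(scores, best)
    shift = float(shifts[0] + refined)
    return CenterEstimate(center=(cols - 1) / 2.0 + shift / 2.0,
                          shift=shift, boundary=boundary)


def estimate_tilt(proj_0: np.ndarray, proj_180: np.ndarray,
                  rows: Optional[Sequence[int]] = None,
                  band: Optional[int] = None,
                  search_halfwidth: int = 50) -> TiltEstimate:
    """Axis tilt from per-row center estimates on a 0/180 projection pair.

    The center is estimated on horizontal bands around sampled rows (default
    5 rows at 10/30/50/70/90% of the detector height), a least-squares line
    ``center(row) = a + b * row`` is fit, and ``tilt = atan(b)`` in degrees.
    """
    p0 = np.atleast_2d(np.asarray(proj_0, dtype=float))
    p180 = np.atleast_2d(np.asarray(proj_180, dtype=float))
    n_rows = p0.shape[0]
    if rows is None:
        rows = [int(round(f * (n_rows - 1))) for f in (0.1, 0.3, 0.5, 0.7, 0.9)]
        rows = sorted(set(rows))
    if len(rows) < 3:
        raise InvalidArgument("need at least 3 sampled rows for a tilt fit")
    if band is None:
        band = max(1, n_rows // 20)
    centers = []
    for r in rows:
        lo = max(0, r - band // 2)
        hi = min(n_rows, lo + max(1, band))
        est = estimate_center(p0[lo:hi], p180[lo:hi],
                              search_halfwidth=search_halfwidth)
        if not est.boundary:
            centers.append((float(r), est.center))
    if len(centers) < 3:
        raise InvalidArgument("fewer than 3 usable rows for the tilt fit")
    rr = np.array([c[0] for c in centers])
    cc = np.array([c[1] for c in centers])
    slope, intercept = np.polyfit(rr, cc, 1)
    return TiltEstimate(tilt=float(np.degrees(np.arctan(slope))),
                        per_row_centers=centers,
                        intercept=float(intercept), slope=float(slope))


def rotate_projections(stack: np.ndarray, angle: float) -> np.ndarray:
    """Rotate every projection frame by ``-angle`` degrees in-plane.

    Used to compensate a measured axis tilt: after
    ``rotate_projections(stack, tilt)``, re-estimating the tilt gives ~0.
    Linear interpolation, shape preserved, edge values extended.
    """
    stack = np.asarray(stack, dtype=float)
    if angle == 0.0:
        return stack.copy()
    if stack.ndim == 2:
        return ndimage.rotate(stack, -angle, reshape=False, order=1,
                              mode="nearest", prefilter=False)
    return ndimage.rotate(stack, -angle, axes=(1, 2), reshape=False, order=1,
                          mode="nearest", prefilter=False)


def estimate_overlap(proj_0: np.ndarray, proj_180: np.ndarray,
                     overlap_range: Optional[Tuple[int, int]] = None,
                     min_correlation: float = 0.5) -> int:
    """Projection overlap of an extended-FOV (half-acquisition) scan.

    With the axis near the right detector edge, the trailing columns of the
    0-degree projection coincide with the leading columns of the mirrored
    180-degree projection. The overlap is the candidate width maximizing the
    normalized cross-correlation of those bands (invariant to global
    intensity scaling). Raises EstimationFailed when no credible peak exists
    (e.g. on a standard centered scan).
    """
    p0 = np.atleast_2d(np.asarray(proj_0, dtype=float))
    p180 = np.atleast_2d(np.asarray(proj_180, dtype=float))
    cols = p0.shape[1]
    mirror = p180[:, ::-1]
    if overlap_range is None:
        overlap_range = (4, cols - 4)
    lo, hi = overlap_range
    ks = np.arange(max(2, lo), min(hi, cols - 1))
    if len(ks) == 0:
        raise InvalidArgument("empty overlap search range")
    scores = np.array([_ncc(p0[:, cols - k:], mirror[:, :k]) for k in ks])
    # near-ties happen for (near-)mirror-symmetric content; the widest
    # perfectly matching band is the physical overlap
    near = scores >= scores.max() - 1.0e-9
    best = int(np.nonzero(near)[0][-1])
    if scores[best] < min_correlation:
        raise EstimationFailed(
            f"no overlap correlation peak above {min_correlation} "
            f"(best {scores[best]:.3f}); is this an extended-FOV scan?")
    if best in (0, len(ks) - 1):
        raise EstimationFailed("overlap correlation peak on search boundary")
    # exact column alignment occurs at k = overlap - 1 (the axis column is
    # shared), so report k* + 1
    return int(ks[best]) + 1


def stitch_pairs(stack: np.ndarray, overlap: int) -> np.ndarray:
    """Stitch 180-degree-opposed projections of a 360-degree half scan.

    For each pair (theta, theta+180): mirror the second frame, blend the
    ``overlap`` shared columns with a linear ramp (weights sum to one, so
    constants are preserved) and concatenate. Output width is
    ``2 * cols - overlap``; the projection count halves.
    """
    stack = np.asarray(stack, dtype=float)
    squeeze = stack.ndim == 2
    if stack.ndim == 2:
        stack = stack[:, None, :]
    n_proj, rows, cols = stack.shape
    if n_proj % 2:
        raise InvalidArgument("half-scan stitching needs an even n_proj")
    if not (0 < overlap < cols):
        raise InvalidArgument(f"overlap {overlap} outside (0, {cols})")
    half = n_proj // 2
    out = np.empty((half, rows, 2 * cols - overlap), dtype=float)
    ramp_up = (np.arange(overlap) + 0.5) / overlap
    ramp_down = 1.0 - ramp_up
    for i in range(half):
        a = stack[i]
        b = stack[i + half][:, ::-1]
        out[i, :, :cols - overlap] = a[:, :cols - overlap]
        out[i, :, cols - overlap:cols] = (a[:, cols - overlap:] * ramp_down
                                          + b[:, :overlap] * ramp_up)
        out[i, :, cols:] = b[:, overlap:]
    return out[:, 0, :] if squeeze else out


def calibrate_scan(normalized: np.ndarray, angles: np.ndarray,
                   halfscan: bool = False,
                   search_halfwidth: int = 50,
                   n_overlap_pairs: int = 5) -> Tuple[ScanGeometry, ScanLog]:
    """Run the full calibration pre-pass on a normalized projection stack.

    Finds the 0/180-degree pair, estimates center (and tilt when the
    detector has enough rows), or the overlap for half scans (median over
    ``n_overlap_pairs`` evenly spaced opposing pairs). Results are returned
    both as a ScanGeometry and as a ScanLog ready to be written next to the
    scan, so downstream stages never re-estimate.
    """
    angles = np.asarray(angles, dtype=float)
    n_proj = len(angles)
    i180 = int(np.argmin(np.abs(((angles - angles[0]) % 360.0) - 180.0)))
    p0, p180 = normalized[0], normalized[i180]

    geometry = ScanGeometry(center=(normalized.shape[-1] - 1) / 2.0)
    if halfscan:
        pairs = np.linspace(0, max(1, i180 - 1), min(n_overlap_pairs, i180),
                            dtype=int)
        estimates = []
        for j in pairs:
            try:
                estimates.append(estimate_overlap(normalized[j],
                                                  normalized[j + i180]))
            except EstimationFailed:
                continue
        if not estimates:
            raise EstimationFailed("overlap estimation failed on all pairs")
        geometry.overlap = int(np.median(estimates))
        geometry.center = normalized.shape[-1] - geometry.overlap / 2.0
    else:
        est = estimate_center(p0, p180, search_halfwidth=search_halfwidth)
        geometry.center = est.center
        if normalized.shape[1] >= 15:
            try:
                tilt = estimate_tilt(p0, p180,
                                     search_halfwidth=search_halfwidth)
                geometry.tilt = tilt.tilt
                geometry.per_row_centers = tilt.per_row_centers
                geometry.center_slope = tilt.slope
                geometry.center_intercept = tilt.intercept
            except InvalidArgument:
                pass

    span = float((angles.max() - angles.min()) * n_proj / max(1, n_proj - 1))
    log = ScanLog(center=geometry.center, tilt=geometry.tilt,
                  overlap=geometry.overlap, n_proj=n_proj,
                  angular_range=round(span, 6))
    return geometry, log
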