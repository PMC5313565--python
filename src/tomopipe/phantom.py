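"""Synthetic phantoms and forward models for every pipeline stage.

This module generates tomographic raw scans with fully known ground truth:
parallel-beam line integrals of analytic phantoms, the detector forward model
(dark current, flat field, Poisson counting noise, zingers, per-column gain
errors), extended field-of-view half scans, Fresnel/TIE propagation contrast
for phase retrieval, and grating-interferometry phase-stepping series.

Conventions used throughout the package
---------------------------------------
* Angles are in degrees, counter-clockwise, with theta = 0 along the +x axis
  of the phantom grid (columns increase with +x).
* The rotation axis projects onto detector column ``center`` (fractional
  column index); the default places it at ``(width - 1) / 2``.
* Phantom values are linear attenuation per pixel, so line integrals are in
  dimensionless units of "attenuation * pixels".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidArgument
from .optics import OpticsConfig

__all__ = [
    "Phantom",
    "GroundTruth",
    "shepp_logan",
    "disc_phantom",
    "asymmetric_phantom",
    "smooth_phantom",
    "forward_project",
    "simulate_acquisition",
    "simulate_scan",
    "simulate_halfscan",
    "simulate_tie_propagation",
    "simulate_phase_propagation",
    "simulate_phase_stepping",
]


@dataclass
class Phantom:
    """Ground-truth object: 2D grid of linear attenuation values [1/pixel]."""

    grid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if not np.all(np.isfinite(self.grid)):
            raise InvalidArgument("phantom grid contains non-finite values")

    @property
    def size(self) -> int:
        return self.grid.shape[-1]


@dataclass
class GroundTruth:
    """Everything injected into a simulated scan, for round-trip testing."""

    true_center: float
    true_tilt: float = 0.0
    true_overlap: Optional[int] = None
    zinger_mask: Optional[np.ndarray] = None
    column_gains: Optional[np.ndarray] = None
    phantom: Optional[Phantom] = None
    projections: Optional[np.ndarray] = None  # clean line integrals
    attenuation_scale: float = 1.0  # applied to the phantom's line integrals

    @property
    def scaled_grid(self) -> Optional[np.ndarray]:
        """Phantom attenuation on the scale the scan actually encodes."""
        if self.phantom is None:
            return None
        return self.phantom.grid * self.attenuation_scale


# Standard modified Shepp-Logan ellipses:
# (additive value, semi-axis a, semi-axis b, x0, y0, rotation angle [deg])
_SHEPP_LOGAN_ELLIPSES = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def shepp_logan(size: int) -> Phantom:
    """Modified Shepp-Logan head phantom on a ``size x size`` grid in [0, 1].

    Deterministic direct evaluation of the ellipse formula; values span
    exactly [0, 1] (background 0, outer rim 1).
    """
    if size < 16:
        raise InvalidArgument(f"phantom size must be >= 16, got {size}")
    half = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    # x to the right, y upward, both in [-1, 1]
    xc = (x - half) / half
    yc = (half - y) / half
    grid = np.zeros((size, size), dtype=float)
    for value, a, b, x0, y0, ang in _SHEPP_LOGAN_ELLIPSES:
        t = np.deg2rad(ang)
        ct, st = np.cos(t), np.sin(t)
        xr = (xc - x0) * ct + (yc - y0) * st
        yr = -(xc - x0) * st + (yc - y0) * ct
        grid[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += value
    return Phantom(np.clip(grid, 0.0, None))


def disc_phantom(size: int, radius: float, value: float = 1.0,
                 cx: float = 0.0, cy: float = 0.0) -> Phantom:
    """Uniform disc of attenuation ``value`` and radius ``radius`` pixels."""
    half = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    r2 = (x - half - cx) ** 2 + (y - half - cy) ** 2
    return Phantom(np.where(r2 <= radius ** 2, value, 0.0))


def asymmetric_phantom(size: int) -> Phantom:
    """Deliberately mirror-asymmetric phantom (disc constellation).

    Registration-based calibration (center, overlap) is ill-posed on
    mirror-symmetric objects, so symmetry-breaking structure is essential
    when exercising those estimators.
    """
    if size < 16:
        raise InvalidArgument(f"phantom size must be >= 16, got {size}")
    r = size / 2.0
    grid = disc_phantom(size, 0.85 * r, 0.3).grid
    grid += disc_phantom(size, 0.22 * r, 0.5, cx=0.40 * r, cy=0.15 * r).grid
    grid += disc_phantom(size, 0.13 * r, 0.7, cx=-0.30 * r, cy=-0.35 * r).grid
    grid += disc_phantom(size, 0.08 * r, 0.9, cx=0.10 * r, cy=0.45 * r).grid
    grid += disc_phantom(size, 0.05 * r, 1.0, cx=-0.50 * r, cy=0.20 * r).grid
    return Phantom(grid)


def smooth_phantom(size: int) -> Phantom:
    """Band-limited phantom (sum of Gaussian blobs), no sharp edges.

    Ring-filter behavior is only well-posed on objects whose angular-mean
    column profile is smooth; this phantom isolates that contract.
    """
    if size < 16:
        raise InvalidArgument(f"phantom size must be >= 16, got {size}")
    h = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    s = size / 128.0
    grid = (0.8 * np.exp(-(((x - h) / (22 * s)) ** 2
                           + ((y - h) / (28 * s)) ** 2))
            + 0.5 * np.exp(-(((x - h - 20 * s) / (10 * s)) ** 2
                             + ((y - h + 15 * s) / (12 * s)) ** 2))
            + 0.4 * np.exp(-(((x - h + 25 * s) / (8 * s)) ** 2
                             + ((y - h - 20 * s) / (9 * s)) ** 2)))
    return Phantom(grid)


def _canvas_size(n: int) -> int:
    """Canvas width covering the grid diagonal, parity-matched to n.

    Equal padding on both sides keeps the grid center exactly on the canvas
    center (the rotation axis), avoiding a spurious half-pixel shift.
    """
    diag = int(np.ceil(n * np.sqrt(2.0))) + 2
    if (diag - n) % 2:
        diag += 1
    return diag


def _padded_canvas(grid: np.ndarray) -> np.ndarray:
    """Embed a square grid in a larger square so rotations never clip."""
    n = grid.shape[-1]
    pad = (_canvas_size(n) - n) // 2
    return np.pad(grid, ((pad, pad), (pad, pad)), mode="constant")


def forward_project(
    phantom: Phantom | np.ndarray,
    angles: Sequence[float],
    center: Optional[float] = None,
    tilt: float = 0.0,
    detector_width: Optional[int] = None,
    n_rows: int = 1,
) -> np.ndarray:
    """Parallel-beam Radon line integrals of a 2D phantom.

    Rays are integrated with linear interpolation (the phantom is rotated by
    the projection angle with first-order interpolation and summed along the
    beam direction). Returns a frame stack of shape ``(n_proj, n_rows,
    detector_width)``; the 2D object is extruded over ``n_rows`` detector
    rows. ``tilt`` rotates each projection frame in-plane (misaligned
    rotation axis), which makes the apparent center drift linearly with the
    detector row.
    """
    grid = phantom.grid if isinstance(phantom, Phantom) else np.asarray(phantom, float)
    angles = np.asarray(angles, dtype=float)
    if np.any(angles < 0.0) or np.any(angles >= 360.0):
        raise InvalidArgument("angles must lie in [0, 360)")
    n = grid.shape[-1]
    if detector_width is None:
        detector_width = _canvas_size(n)
    if center is None:
        center = (detector_width - 1) / 2.0
    if not (0.0 <= center < detector_width):
        raise InvalidArgument(
            f"center {center} outside detector of width {detector_width}")

    canvas = _padded_canvas(grid)
    d = canvas.shape[0]
    prof_axis = np.arange(d) - (d - 1) / 2.0  # object x-offset of profile bins
    det_offsets = np.arange(detector_width) - center

    sino = np.empty((len(angles), detector_width), dtype=float)
    for i, theta in enumerate(angles):
        if theta == 0.0:
            rot = canvas
        else:
            rot = ndimage.rotate(canvas, -theta, reshape=False, order=1,
                                 mode="constant", cval=0.0, prefilter=False)
        profile = rot.sum(axis=0)
        sino[i] = np.interp(det_offsets, prof_axis, profile, left=0.0, right=0.0)

    frames = np.repeat(sino[:, None, :], n_rows, axis=1)
    if tilt != 0.0:
        frames = ndimage.rotate(frames, tilt, axes=(1, 2), reshape=False,
                                order=1, mode="nearest", prefilter=False)
    return frames


def _default_flat(rows: int, cols: int) -> np.ndarray:
    """Smooth synchrotron-like beam profile (brighter in the middle)."""
    c = np.arange(cols)
    r = np.arange(rows)
    pc = 0.8 + 0.4 * np.exp(-((c - cols / 2.0) ** 2) / (2.0 * (cols / 3.0) ** 2))
    pr = 0.9 + 0.2 * np.exp(-((r - rows / 2.0) ** 2) / (2.0 * (rows / 2.5) ** 2))
    return np.outer(pr, pc)


def simulate_acquisition(
    projections: np.ndarray,
    flat_profile: Optional[np.ndarray] = None,
    dark_level: float = 20.0,
    photon_count: float = 1.0e4,
    zinger_rate: float = 0.0,
    column_gains: Optional[np.ndarray] = None,
    gains_in_flats: bool = False,
    seed: int = 0,
    n_flats: int = 10,
    n_darks: int = 5,
    read_noise: float = 2.0,
    poisson: bool = True,
):
    """Detector forward model: raw frames from clean line integrals.

    ``frame = dark_level + gains * flat * photon_count * exp(-projection)``
    with Poisson noise on the detected counts and Gaussian read noise from
    the dark current; zingers are injected on the raw frames as
    multiplicative spikes (10x the local level, hence always >= 5x). The
    default ``photon_count = 1e4`` gives flat-field SNR ~ 100.

    ``column_gains`` model per-column response drift *after* the flat
    fields were acquired (the minimal cause of ring artifacts): by default
    the flats are generated without them, so flat-field correction leaves
    residual vertical sinogram stripes. Set ``gains_in_flats=True`` for a
    static gain pattern that normalization removes exactly.

    Returns ``(RawScan, GroundTruth)``; fully reproducible from ``seed``.
    """
    from .io_formats import RawScan

    proj = np.asarray(projections, dtype=float)
    if proj.ndim == 2:
        proj = proj[:, None, :]
    n_proj, rows, cols = proj.shape
    if photon_count <= 0:
        raise InvalidArgument("photon_count must be > 0")
    if flat_profile is None:
        flat_profile = _default_flat(rows, cols)
    flat_profile = np.broadcast_to(np.asarray(flat_profile, float), (rows, cols))
    if np.any(flat_profile <= 0):
        raise InvalidArgument("flat_profile must be strictly positive")
    if column_gains is None:
        gains = np.ones(cols)
    else:
        gains = np.asarray(column_gains, dtype=float)
        if np.any(gains <= 0):
            raise InvalidArgument("column_gains must be > 0")

    rng = np.random.default_rng(seed)
    beam = gains[None, :] * flat_profile * photon_count
    flat_beam = beam if gains_in_flats else flat_profile * photon_count

    def detect(counts: np.ndarray) -> np.ndarray:
        if poisson:
            out = rng.poisson(counts).astype(float)
            out += dark_level + rng.normal(0.0, read_noise, size=counts.shape)
            return np.clip(out, 0.0, None)
        return counts + dark_level

    frames = detect(beam[None, :, :] * np.exp(-proj))
    zmask = rng.random(frames.shape) < zinger_rate
    frames[zmask] *= 10.0  # direct X-ray hit: far above local level
    flats = detect(np.broadcast_to(flat_beam, (n_flats, rows, cols)).copy())
    darks = dark_level + (rng.normal(0.0, read_noise, (n_darks, rows, cols))
                          if poisson else 0.0)
    darks = np.clip(np.broadcast_to(darks, (n_darks, rows, cols)), 0.0, None)

    if poisson:
        frames = np.rint(frames).astype(np.uint32)
        flats = np.rint(flats).astype(np.uint32)
        darks = np.rint(darks).astype(np.uint32)

    scan = RawScan(
        projections=frames,
        flats=flats,
        darks=np.array(darks),
        angles=np.linspace(0.0, 180.0, n_proj, endpoint=False),
        metadata={"photon_count": photon_count, "dark_level": dark_level},
    )
    truth = GroundTruth(true_center=(cols - 1) / 2.0, zinger_mask=zmask,
                        column_gains=gains, projections=proj)
    return scan, truth


def simulate_scan(
    phantom: Phantom,
    n_proj: int = 200,
    center: Optional[float] = None,
    tilt: float = 0.0,
    n_rows: int = 1,
    detector_width: Optional[int] = None,
    angular_range: float = 180.0,
    max_attenuation: Optional[float] = 2.5,
    **acq_kwargs,
):
    """Full synthetic scan of a phantom: projections + detector model.

    Convenience wrapper combining :func:`forward_project` and
    :func:`simulate_acquisition`. Line integrals are rescaled so the densest
    ray attenuates by ``max_attenuation`` (transmission ~ e^-2.5, a typical
    well-exposed sample; ``None`` disables the rescaling); the factor is
    recorded in ``GroundTruth.attenuation_scale`` and the attenuation the
    scan encodes is ``GroundTruth.scaled_grid``.
    """
    angles = np.linspace(0.0, angular_range, n_proj, endpoint=False)
    frames = forward_project(phantom, angles, center=center, tilt=tilt,
                             detector_width=detector_width, n_rows=n_rows)
    scale = 1.0
    if max_attenuation is not None and frames.max() > 0:
        scale = max_attenuation / frames.max()
        frames = frames * scale
    scan, truth = simulate_acquisition(frames, **acq_kwargs)
    scan.angles = angles
    w = frames.shape[-1]
    truth.true_center = (w - 1) / 2.0 if center is None else float(center)
    truth.true_tilt = float(tilt)
    truth.phantom = phantom
    truth.attenuation_scale = scale
    return scan, truth


def simulate_halfscan(
    phantom: Phantom,
    n_proj: int = 400,
    overlap: int = 40,
    n_rows: int = 1,
    max_attenuation: Optional[float] = 2.5,
    **acq_kwargs,
):
    """Extended-FOV scan: 360 degrees with the axis near the right edge.

    The detector covers roughly half the object plus an overlap band of
    ``overlap`` columns around the rotation axis, so projections at theta and
    theta+180 can be stitched into a double-width 180-degree scan. The ground
    truth records ``true_overlap = 2 * (W - true_center)``.
    """
    if overlap % 2:
        raise InvalidArgument("overlap must be even")
    n = phantom.size
    angles = np.linspace(0.0, 360.0, n_proj, endpoint=False)
    center = n // 2 + 4 + overlap // 2       # axis-to-left-edge distance
    width = center + overlap // 2            # axis near the right edge
    # full (untruncated) projections with an odd detector wide enough for
    # the crop, so the axis sits on an integer column and the crop is exact
    d = max(int(np.ceil(n * np.sqrt(2.0))) + 2, 2 * center + 1)
    if d % 2 == 0:
        d += 1
    full = forward_project(phantom, angles, detector_width=d, n_rows=n_rows)
    cf = (d - 1) // 2
    if width > d or center >= d:
        raise InvalidArgument("rotation axis outside the simulated detector")
    start = cf - center
    frames = full[:, :, start:start + width]
    scale = 1.0
    if max_attenuation is not None and frames.max() > 0:
        scale = max_attenuation / frames.max()
        frames = frames * scale
    scan, truth = simulate_acquisition(frames, **acq_kwargs)
    scan.angles = angles
    scan.metadata["halfscan"] = True
    truth.true_center = float(center)
    truth.true_overlap = int(2 * (width - center))
    truth.phantom = phantom
    truth.attenuation_scale = scale
    return scan, truth


def _k_squared(shape, pixel_size: float) -> np.ndarray:
    """|k|^2 = (2 pi)^2 (u^2 + v^2) with u, v in cycles/length."""
    u = np.fft.fftfreq(shape[-1], d=pixel_size)
    v = np.fft.fftfreq(shape[-2], d=pixel_size)
    return (2.0 * np.pi) ** 2 * (u[None, :] ** 2 + v[:, None] ** 2)


def simulate_tie_propagation(thickness_map: np.ndarray,
                             optics: OpticsConfig) -> np.ndarray:
    """Linear TIE propagation of a single-material object.

    The contact image ``exp(-mu T)`` is multiplied in Fourier space by
    ``1 + (delta z / mu) |k|^2``, so single-distance (Paganin) retrieval is
    its exact inverse on the same grid.
    """
    if optics.beta <= 0:
        raise InvalidArgument("beta must be > 0")
    if optics.distance < 0:
        raise InvalidArgument("propagation distance must be >= 0")
    t = np.asarray(thickness_map, dtype=float)
    contact = np.exp(-optics.mu * t)
    if optics.distance == 0.0:
        return contact
    k2 = _k_squared(t.shape, optics.pixel_size)
    filt = 1.0 + (optics.delta * optics.distance / optics.mu) * k2
    return np.fft.ifft2(np.fft.fft2(contact) * filt).real


def simulate_phase_propagation(phase_map: np.ndarray,
                               optics: OpticsConfig) -> np.ndarray:
    """Near-field intensity of a pure phase object, linear TIE order.

    ``phase_map`` is the (positive) phase retardation magnitude in radians;
    the propagated intensity is ``I = 1 + (lambda z / 2 pi) laplacian(phi)``,
    evaluated spectrally. MBA/Moosmann retrieval inverts this model.
    """
    if optics.distance < 0:
        raise InvalidArgument("propagation distance must be >= 0")
    phi = np.asarray(phase_map, dtype=float)
    k2 = _k_squared(phi.shape, optics.pixel_size)
    lam = optics.wavelength
    lap = np.fft.ifft2(np.fft.fft2(phi) * (-k2)).real
    return 1.0 + (lam * optics.distance / (2.0 * np.pi)) * lap


def simulate_phase_stepping(
    a0_map: np.ndarray,
    visibility_map: np.ndarray,
    phase_map: np.ndarray,
    n_steps: int,
    seed: Optional[int] = None,
    poisson: bool = False,
) -> np.ndarray:
    """Grating-interferometry stepping curves, one cosine period in S steps.

    Per pixel and step ``s``: ``I_s = a0 (1 + V cos(2 pi s / S + phi))``.
    Returns a frame stack of shape ``(n_steps, rows, cols)``.
    """
    if n_steps < 3:
        raise InvalidArgument("need n_steps >= 3 to identify the harmonic")
    a0 = np.asarray(a0_map, dtype=float)
    vis = np.asarray(visibility_map, dtype=float)
    phi = np.asarray(phase_map, dtype=float)
    if np.any(vis < 0) or np.any(vis > 1):
        raise InvalidArgument("visibility must lie in [0, 1]")
    s = np.arange(n_steps)[:, None, None]
    frames = a0 * (1.0 + vis * np.cos(2.0 * np.pi * s / n_steps + phi))
    if poisson:
        rng = np.random.default_rng(seed)
        frames = rng.poisson(frames).astype(float)
    return frames
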