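"""Grating-interferometry phase-stepping analysis and the GI pipeline.

Scanning one grating over its period in S equidistant steps samples a cosine
fringe per pixel: ``I_s = a0 (1 + V cos(2 pi s / S + phi))``. A pixelwise
FFT over the stepping axis separates the mean (a0), the fringe visibility
(V = 2|X1| / |X0|) and the fringe phase (phi = arg X1); ratios against a
reference (no-sample) scan yield the three complementary contrasts:

* absorption  = a0_sample / a0_reference      (-ln before reconstruction)
* DPC         = wrap(phi_sample - phi_ref)    (Hilbert-filtered recon)
* dark field  = V_sample / V_reference        (-ln before reconstruction)

Residual horizontal stripes on DPC projections (beam vibrations) are
removed with the wavelet-FFT stripe filter applied to the transposed image.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .artifacts import ring_remove_wavelet_fft
from .errors import InvalidArgument
from .recon import FilterSpec, gridrec

__all__ = ["HarmonicMaps", "analyze_steps", "extract_contrasts",
           "destripe_dpc", "wrap_phase", "gi_pipeline"]

#: first-harmonic magnitudes below this fraction of a0 give undefined phase
PHASE_VALID_FRACTION = 1.0e-12


@dataclass
class HarmonicMaps:
    """Per-pixel stepping-curve harmonics of one stepped acquisition."""

    a0: np.ndarray          # mean intensity
    a1_mag: np.ndarray      # first-harmonic magnitude
    phi: np.ndarray         # first-harmonic phase, wrapped to (-pi, pi]
    visibility: np.ndarray  # V = 2 |X1| / |X0|
    valid: np.ndarray       # False where the phase is undefined (V ~ 0)


def analyze_steps(frames: np.ndarray) -> HarmonicMaps:
    """Pixelwise FFT analysis of a phase-stepping frame stack (S, rows, cols).

    Exact (machine precision) for noiseless single-harmonic curves for any
    S >= 3 and any phi: ``a0 = X0 / S``, ``a1 = 2 |X1| / S``,
    ``phi = arg X1``. Pixels with a vanishing first harmonic get phi = 0 and
    are flagged invalid.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[:, None, :]
    s = frames.shape[0]
    if s < 3:
        raise InvalidArgument("phase stepping needs >= 3 steps")
    spectrum = np.fft.fft(frames, axis=0)
    a0 = spectrum[0].real / s
    a1_mag = 2.0 * np.abs(spectrum[1]) / s
    valid = a1_mag > PHASE_VALID_FRACTION * np.maximum(np.abs(a0), 1e-300)
    phi = np.where(valid, np.angle(spectrum[1]), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vis = np.where(a0 > 0, a1_mag / np.where(a0 > 0, a0, 1.0), 0.0)
    return HarmonicMaps(a0=a0, a1_mag=a1_mag, phi=phi, visibility=vis,
                        valid=valid)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    out = np.asarray(phi, dtype=float)
    wrapped = -((-out + np.pi) % (2.0 * np.pi) - np.pi)
    return wrapped


def extract_contrasts(sample: HarmonicMaps, reference: HarmonicMaps
                      ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absorption, DPC and dark-field projections from sample vs reference.

    Pixels with zero reference intensity or visibility are masked (set to
    NaN in the affected contrast). Returns ``(absorption, dpc, darkfield)``.
    """
    if sample.a0.shape != reference.a0.shape:
        raise InvalidArgument("sample/reference shapes differ")
    ref_ok = reference.a0 > 0
    vis_ok = ref_ok & (reference.visibility > 0) & reference.valid
    with np.errstate(divide="ignore", invalid="ignore"):
        absorption = np.where(ref_ok, sample.a0 / np.where(ref_ok, reference.a0, 1.0),
                              np.nan)
        dark = np.where(vis_ok,
                        sample.visibility / np.where(vis_ok, reference.visibility, 1.0),
                        np.nan)
    dpc = np.where(vis_ok, wrap_phase(sample.phi - reference.phi), np.nan)
    return absorption, dpc, dark


def destripe_dpc(dpc: np.ndarray, wavelet: str = "db25", n_levels: int = 4,
                 damping_sigma: float = 2.0) -> np.ndarray:
    """Remove residual horizontal stripes from one DPC projection.

    By construction this is the wavelet-FFT ring filter applied to the
    transposed image (horizontal stripes become vertical ones) and
    transposed back.
    """
    return ring_remove_wavelet_fft(np.asarray(dpc, float).T, wavelet,
                                   n_levels, damping_sigma).T


def _analyze_one_angle(frames: np.ndarray, ref: HarmonicMaps, idx: int,
                       destripe: bool) -> np.ndarray:
    """Stepping analysis + contrast extraction for one angular position.

    Module-level (picklable) so the per-angle work can be distributed to a
    process pool with results identical to the serial path.
    """
    maps = analyze_steps(frames)
    proj = extract_contrasts(maps, ref)[idx]
    proj = np.nan_to_num(proj, nan=1.0 if idx != 1 else 0.0)
    if idx == 1 and destripe:
        proj = destripe_dpc(proj)
    return proj


def gi_pipeline(
    sample_steps: np.ndarray,
    reference_steps: np.ndarray,
    angles: Sequence[float],
    contrast: str = "absorption",
    center: Optional[float] = None,
    spec: Optional[FilterSpec] = None,
    rows: Optional[Sequence[int]] = None,
    destripe: bool = True,
    transmission_floor: float = 1.0e-6,
    backend: str = "serial",
    processes: int = 2,
) -> list:
    """Full GI branch: stepping analysis -> contrast -> reconstruction.

    ``sample_steps`` has shape (n_angles, n_steps, rows, cols); one
    reference stepping set serves all angles. The requested contrast decides
    the reconstruction filter: -ln + ramp filter for absorption and dark
    field, the Hilbert kernel (no ln) for DPC. Per-angle analysis may run
    serially or on a process pool with bit-identical results.
    """
    from .pipeline import map_backend

    if contrast not in ("absorption", "dpc", "darkfield"):
        raise InvalidArgument(
            f"contrast must be absorption|dpc|darkfield, got {contrast!r}")
    sample_steps = np.asarray(sample_steps, dtype=float)
    if sample_steps.ndim != 4:
        raise InvalidArgument(
            "sample_steps must be (n_angles, n_steps, rows, cols)")
    if reference_steps is None:
        raise InvalidArgument("a reference stepping set is required")
    ref = analyze_steps(np.asarray(reference_steps, dtype=float))

    idx = {"absorption": 0, "dpc": 1, "darkfield": 2}[contrast]
    fn = functools.partial(_analyze_one_angle, ref=ref, idx=idx,
                           destripe=destripe)
    projections = np.stack(map_backend(fn, list(sample_steps),
                                       backend=backend, processes=processes))
    n_rows, n_cols = projections.shape[1:]
    if rows is None:
        rows = range(n_rows)
    if center is None:
        center = (n_cols - 1) / 2.0
    if spec is None:
        spec = FilterSpec("hilbert") if contrast == "dpc" else FilterSpec()

    slices = []
    for r in rows:
        sino = projections[:, r, :]
        if contrast != "dpc":
            sino = -np.log(np.clip(sino, transmission_floor, None))
        rec, _ = gridrec(sino, angles, center=center, spec=spec)
        rec.row = int(r)
        slices.append(rec)
    return slices
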