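"""Single-distance phase retrieval on normalized projections.

Three retrieval methods are provided for near-field propagation contrast:

* Paganin: single-material low-pass filter yielding projected thickness,
  optionally followed by a Gaussian/Tikhonov deconvolution that partially
  restores the resolution lost to the low-pass.
* MBA (modified Bronnikov): regularized Laplacian inversion of the intensity
  deviation, yielding a phase map.
* Moosmann (linear order): the same transport-of-intensity inversion for a
  pure phase object, without the Bronnikov regularizer.

All methods pad frames symmetrically to the next power of 2 per dimension
before the FFT (a size that is already a power of 2 is kept) and crop back
afterwards. The sign convention makes retrieved phase positive for thicker
phase-advancing material; the matching forward model lives in
``tomopipe.phantom.simulate_phase_propagation``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgument
from .optics import OpticsConfig

__all__ = ["RetrievalConfig", "paganin", "deconvolve", "mba", "moosmann",
           "retrieve"]

INTENSITY_FLOOR = 1.0e-6


@dataclass
class RetrievalConfig:
    """Phase-retrieval method selection and parameters."""

    method: str = "paganin"  # paganin | mba | moosmann
    deconv_enabled: bool = False
    deconv_sigma: float = 1.0
    deconv_reg: float = 1.0e-3
    mba_alpha: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.method not in ("paganin", "mba", "moosmann"):
            raise InvalidArgument(
                f"method must be paganin|mba|moosmann, got {self.method!r}")
        if self.deconv_reg <= 0:
            raise InvalidArgument("deconv_reg must be > 0")
        if self.method == "mba" and self.mba_alpha <= 0:
            raise InvalidArgument("mba_alpha must be > 0")


def _next_pow2(n: int) -> int:
    return 1 << max(0, (n - 1).bit_length())


def _pad(frame: np.ndarray):
    rows, cols = frame.shape
    pr, pc = _next_pow2(rows) - rows, _next_pow2(cols) - cols
    if pr == 0 and pc == 0:
        return frame, (slice(None), slice(None))
    lo_r, lo_c = pr // 2, pc // 2
    padded = np.pad(frame, ((lo_r, pr - lo_r), (lo_c, pc - lo_c)),
                    mode="symmetric")
    return padded, (slice(lo_r, lo_r + rows), slice(lo_c, lo_c + cols))


def _k_squared(shape, pixel_size: float) -> np.ndarray:
    u = np.fft.fftfreq(shape[-1], d=pixel_size)
    v = np.fft.fftfreq(shape[-2], d=pixel_size)
    return (2.0 * np.pi) ** 2 * (u[None, :] ** 2 + v[:, None] ** 2)


def paganin(intensity: np.ndarray, optics: OpticsConfig,
            floor: float = INTENSITY_FLOOR) -> np.ndarray:
    """Single-material thickness map from one normalized projection.

    ``T = -(1/mu) ln( F^-1[ F[I/I0] / (1 + (delta z / mu) |k|^2) ] )`` with
    ``mu = 4 pi beta / lambda``. At z = 0 the filter is identity and
    ``T = -ln(I)/mu`` exactly. Output in the length unit of
    ``optics.pixel_size`` (meters).
    """
    if optics.mu <= 0:
        raise InvalidArgument("mu must be > 0")
    frame = np.clip(np.asarray(intensity, dtype=float), floor, None)
    padded, crop = _pad(frame)
    if optics.distance > 0:
        k2 = _k_squared(padded.shape, optics.pixel_size)
        filt = 1.0 + (optics.delta * optics.distance / optics.mu) * k2
        padded = np.fft.ifft2(np.fft.fft2(padded) / filt).real
    smoothed = np.clip(padded[crop], floor, None)
    return -np.log(smoothed) / optics.mu


def deconvolve(image: np.ndarray, sigma: float, reg: float = 1.0e-3) -> np.ndarray:
    """Gaussian/Tikhonov deconvolution restoring high-frequency content.

    The spectrum is multiplied by ``G / (G^2 + reg)`` for a Gaussian kernel
    of width ``sigma`` pixels, normalized so the DC gain is exactly 1 (the
    image mean is preserved).
    """
    if sigma <= 0:
        raise InvalidArgument("sigma must be > 0")
    if reg <= 0:
        raise InvalidArgument("reg must be > 0")
    frame = np.asarray(image, dtype=float)
    padded, crop = _pad(frame)
    u = np.fft.fftfreq(padded.shape[1])
    v = np.fft.fftfreq(padded.shape[0])
    k2 = u[None, :] ** 2 + v[:, None] ** 2
    g = np.exp(-2.0 * np.pi ** 2 * sigma ** 2 * k2)
    h = g / (g ** 2 + reg)
    h /= h[0, 0]  # unit DC gain
    return np.fft.ifft2(np.fft.fft2(padded) * h).real[crop]


def mba(intensity: np.ndarray, optics: OpticsConfig,
        alpha: float = 1.0e-3) -> np.ndarray:
    """Modified Bronnikov phase map from one normalized projection.

    ``phi = -(2 pi / (lambda z)) F^-1[ F[I/I0 - 1] /
    (|k|^2 + alpha (2 pi / pixel_size)^2) ]``; ``alpha`` is the
    dimensionless regularizer (a fraction of the squared Nyquist-scale
    frequency). Retrieved phase is positive for thicker phase-advancing
    material.
    """
    if optics.distance == 0:
        raise InvalidArgument("MBA kernel is singular at z = 0")
    if alpha <= 0:
        raise InvalidArgument("alpha must be > 0")
    frame = np.asarray(intensity, dtype=float) - 1.0
    padded, crop = _pad(frame)
    k2 = _k_squared(padded.shape, optics.pixel_size)
    denom = k2 + alpha * (2.0 * np.pi / optics.pixel_size) ** 2
    coeff = -2.0 * np.pi / (optics.wavelength * optics.distance)
    return coeff * np.fft.ifft2(np.fft.fft2(padded) / denom).real[crop]


def moosmann(intensity: np.ndarray, optics: OpticsConfig) -> np.ndarray:
    """Linear-order pure-phase TIE inversion of one normalized projection.

    ``phi = -F^-1[ F[I/I0 - 1] / ((lambda z / 2 pi) |k|^2) ]`` with the
    undefined DC term set to zero (the mean phase is not recoverable from
    propagation contrast). Higher-order nonlinear corrections are out of
    scope; this is the same kernel family as MBA in the alpha -> 0 limit.
    """
    if optics.distance == 0:
        raise InvalidArgument("TIE kernel is singular at z = 0")
    frame = np.asarray(intensity, dtype=float) - 1.0
    padded, crop = _pad(frame)
    k2 = _k_squared(padded.shape, optics.pixel_size)
    denom = (optics.wavelength * optics.distance / (2.0 * np.pi)) * k2
    denom[0, 0] = np.inf  # zero out the undefined DC component
    return -np.fft.ifft2(np.fft.fft2(padded) / denom).real[crop]


def retrieve(intensity: np.ndarray, optics: OpticsConfig,
             config: RetrievalConfig) -> np.ndarray:
    """Apply the configured retrieval method to one normalized projection."""
    if config.method == "paganin":
        out = paganin(intensity, optics)
        if config.deconv_enabled:
            out = deconvolve(out, config.deconv_sigma, config.deconv_reg)
        return out
    if config.method == "mba":
        return mba(intensity, optics, alpha=config.mba_alpha)
    return moosmann(intensity, optics)
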