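"""Beam/optics parameters shared by propagation simulation and retrieval."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgument

# hc in keV * m (CODATA): lambda [m] = HC_KEV_M / E [keV]
HC_KEV_M = 1.2398419843320026e-9


@dataclass
class OpticsConfig:
    """X-ray energy, propagation geometry and single-material constants.

    Parameters
    ----------
    energy : float
        Photon energy in keV.
    distance : float
        Sample-to-detector propagation distance in meters.
    pixel_size : float
        Detector pixel size in meters.
    delta, beta : float
        Refractive index decrement and absorption index of the (single)
        material: n = 1 - delta + i beta.
    """

    energy: float
    distance: float
    pixel_size: float
    delta: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("energy", "pixel_size", "delta", "beta"):
            if getattr(self, name) <= 0:
                raise InvalidArgument(f"{name} must be > 0")
        if self.distance < 0:
            raise InvalidArgument("distance must be >= 0")
        ratio = self.delta / self.beta
        if not (10.0 <= ratio <= 1.0e4):
            warnings.warn(
                f"delta/beta = {ratio:.3g} outside the typical 10-1e4 range",
                stacklevel=2)

    @property
    def wavelength(self) -> float:
        """Wavelength lambda in meters."""
        return HC_KEV_M / self.energy

    @property
    def mu(self) -> float:
        """Linear attenuation coefficient mu = 4 pi beta / lambda [1/m]."""
        return 4.0 * np.pi * self.beta / self.wavelength
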