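"""Sampling grids for scalar wave propagation.

A :class:`GridSpec` describes the transverse detector/object lattice
(pixel pitch, wavelength, surrounding-medium refractive index); a
:class:`DepthGrid` describes the axial slice stack used by the
multi-slice forward model.  Both are plain metadata containers — the
complex field itself travels as a numpy array alongside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.constants as const


class InvalidConfigurationError(ValueError):
    """Raised for physically meaningless optical parameters."""


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength (m) for an X-ray energy in keV.

    Uses CODATA constants: lambda = h c / E.
    """
    if energy_kev <= 0:
        raise InvalidConfigurationError("photon energy must be positive")
    return const.h * const.c / (energy_kev * 1e3 * const.e)


@dataclass(frozen=True)
class GridSpec:
    """Transverse sampling lattice of an ``ny x nx`` complex wavefield.

    Parameters
    ----------
    nx, ny : int
        Grid width L and height M in pixels.
    dx, dy : float
        Pixel pitch in metres.
    wavelength : float
        Vacuum wavelength in metres.
    n_med : float
        Real refractive index of the surrounding medium (>= 1).
    """

    nx: int
    ny: int
    dx: float
    dy: float
    wavelength: float
    n_med: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise InvalidConfigurationError("grid must be at least 2x2 pixels")
        if self.dx <= 0 or self.dy <= 0:
            raise InvalidConfigurationError("pixel pitch must be positive")
        if self.wavelength <= 0:
            raise InvalidConfigurationError("wavelength must be positive")
        if not np.isfinite(self.n_med) or self.n_med < 1:
            raise InvalidConfigurationError("n_med must be finite and >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """Spatial-frequency lattice (fy, fx) in cycles/m, unshifted FFT order."""
        fx = np.fft.fftfreq(self.nx, d=self.dx)
        fy = np.fft.fftfreq(self.ny, d=self.dy)
        return fy, fx

    def incident_field(self, dtype=np.complex128) -> np.ndarray:
        """Unit plane-wave illumination: the background-normalized incident beam."""
        return np.ones(self.shape, dtype=dtype)


@dataclass(frozen=True)
class DepthGrid:
    """Axial slice stack centred on the approximate object depth.

    ``z_prime`` is the distance of the object plane from the detector
    (detector at z = 0), ``dz`` the slice spacing and ``n_slices`` the
    (odd) number of slices.  Slices span ``[z' - h dz, z' + h dz]`` with
    half-width ``h = (n_slices - 1) / 2``; the default 81 slices give the
    +/- 40 dz training window.
    """

    z_prime: float
    dz: float
    n_slices: int = 81

    def __post_init__(self) -> None:
        if self.dz <= 0:
            raise InvalidConfigurationError("dz must be positive")
        if self.n_slices < 1 or self.n_slices % 2 == 0:
            raise InvalidConfigurationError("n_slices must be a positive odd integer")
        if self.z1 <= 0:
            raise InvalidConfigurationError(
                "slice stack must lie strictly between detector and source"
            )

    @property
    def half_width(self) -> int:
        return (self.n_slices - 1) // 2

    @property
    def z1(self) -> float:
        """Position of the first (detector-side) slice."""
        return self.z_prime - self.half_width * self.dz

    @property
    def zN(self) -> float:
        """Position of the last (source-side) slice."""
        return self.z_prime + self.half_width * self.dz

    @property
    def positions(self) -> np.ndarray:
        return self.z1 + self.dz * np.arange(self.n_slices)

    @property
    def center_index(self) -> int:
        """Index of the slice at z'."""
        return self.half_width

    def window_indices(self, w_z: int) -> np.ndarray:
        """Slice indices within the axial window z' +/- w_z dz."""
        c = self.center_index
        if w_z < 0 or c - w_z < 0 or c + w_z >= self.n_slices:
            raise InvalidConfigurationError("axial window exceeds the depth grid")
        return np.arange(c - w_z, c + w_z + 1)
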