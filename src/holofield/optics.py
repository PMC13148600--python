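"""Angular-spectrum propagation and the multi-slice scalar forward model.

The angular spectrum method (ASM) propagates a monochromatic scalar
field between parallel planes exactly (within the discrete band):

    U(z + d) = F^-1{ F{U(z)} . exp[ i 2 pi (n/lambda) d sqrt(1 - (lambda fx/n)^2
                                                             - (lambda fy/n)^2) ] }

Evanescent components (negative radicand) are zeroed.  A weakly
refracting object volume is modelled as a stack of thin slices, each
multiplying the field by ``exp(i phi o_phi - A o_A)`` before a
free-space ASM step of one slice spacing; the final slice is followed by
a single free-space jump to the detector plane.

The module also supplies the adjoint (reverse-mode) pass of the
multi-slice model, which is what makes the neural-field training loop
differentiable end to end without an autodiff framework.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DepthGrid, GridSpec, InvalidConfigurationError


class InvalidFieldError(ValueError):
    """Raised when a wavefield contains NaN/Inf samples."""


class InvalidHologramError(ValueError):
    """Raised for holograms with negative intensities."""


@dataclass
class ObjectVolume:
    """Voxelized object occupancy with global phase/absorbance coefficients.

    ``o_phi`` and ``o_A`` are occupancy arrays in [0, 1] of shape
    (n_slices, ny, nx).  ``phi`` (rad, negative for a refractive-index
    decrement delta > 0) and ``A`` (dimensionless, >= 0) are the
    per-fully-occupied-voxel phase shift and amplitude absorbance; for a
    one-slice-thick object they equal the total column values
    ``phi = -2 pi delta t / lambda`` and ``A = 2 pi kappa t / lambda``.
    """

    o_phi: np.ndarray
    o_A: np.ndarray
    phi: float
    A: float

    def __post_init__(self) -> None:
        self.o_phi = np.asarray(self.o_phi)
        self.o_A = np.asarray(self.o_A)
        if self.o_phi.shape != self.o_A.shape or self.o_phi.ndim != 3:
            raise ValueError("o_phi and o_A must share a (n_slices, ny, nx) shape")
        if self.A < 0:
            raise InvalidConfigurationError("absorbance coefficient must be >= 0")
        for name, arr in (("o_phi", self.o_phi), ("o_A", self.o_A)):
            if arr.size and (arr.min() < -1e-6 or arr.max() > 1 + 1e-6):
                raise ValueError(f"{name} occupancy must lie in [0, 1]")

    @property
    def n_slices(self) -> int:
        return self.o_phi.shape[0]

    @classmethod
    def empty(cls, grid: GridSpec, n_slices: int, phi: float = 0.0, A: float = 0.0):
        z = np.zeros((n_slices, grid.ny, grid.nx))
        return cls(z, z.copy(), phi, A)


def asm_transfer(grid: GridSpec, distance: float) -> np.ndarray:
    """ASM transfer function for one free-space step of ``distance`` metres.

    Returned in unshifted FFT ordering; evanescent frequencies are set
    to exactly 0.  ``distance`` may be negative (back-propagation).
    """
    if not np.isfinite(distance):
        raise InvalidConfigurationError("propagation distance must be finite")
    fy, fx = grid.frequencies()
    lam = grid.wavelength / grid.n_med  # wavelength in the medium
    radicand = 1.0 - (lam * fx[None, :]) ** 2 - (lam * fy[:, None]) ** 2
    propagating = radicand > 0
    kz = np.zeros(grid.shape)
    np.sqrt(radicand, out=kz, where=propagating)
    kernel = np.exp(1j * 2.0 * np.pi / lam * distance * kz)
    kernel[~propagating] = 0.0
    return kernel


def propagate(field: np.ndarray, grid: GridSpec, distance: float,
              kernel: np.ndarray | None = None) -> np.ndarray:
    """Free-space ASM propagation of a complex field by ``distance``."""
    field = np.asarray(field)
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} does not match grid {grid.shape}")
    if not np.all(np.isfinite(field)):
        raise InvalidFieldError("field contains NaN or Inf")
    if kernel is None:
        kernel = asm_transfer(grid, distance)
    return np.fft.ifft2(np.fft.fft2(field) * kernel)


def _adjoint_propagate(g: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # adjoint of F^-1 diag(K) F is F^-1 diag(conj K) F (FFT scalings cancel)
    return np.fft.ifft2(np.fft.fft2(g) * np.conj(kernel))


def transmission(vol: ObjectVolume, i: int) -> np.ndarray:
    """Complex transmission of slice ``i``: exp(i phi o_phi - A o_A)."""
    return np.exp(1j * vol.phi * vol.o_phi[i] - vol.A * vol.o_A[i])


def multislice_forward(vol: ObjectVolume, depth: DepthGrid, grid: GridSpec,
                       return_field: bool = False):
    """Detector-plane intensity |U_0|^2 of a unit beam through the volume.

    The beam enters at the source-side slice z_N with U_N = 1, is
    modulated and stepped slice to slice toward z_1, and finally jumps
    the object-free gap z_1 -> detector in a single ASM step.
    """
    if vol.n_slices != depth.n_slices:
        raise ValueError("volume slice count does not match depth grid")
    if vol.o_phi.shape[1:] != grid.shape:
        raise ValueError("volume transverse shape does not match grid")
    U0 = _multislice_field(vol, depth, grid)
    intensity = np.abs(U0) ** 2
    return (intensity, U0) if return_field else intensity


def _multislice_field(vol: ObjectVolume, depth: DepthGrid, grid: GridSpec,
                      cache: list | None = None) -> np.ndarray:
    k_dz = asm_transfer(grid, depth.dz)
    U = grid.incident_field()
    for i in range(depth.n_slices - 1, -1, -1):
        V = U * transmission(vol, i)
        if cache is not None:
            cache.append((U, V))
        U = propagate(V, grid, depth.dz if i > 0 else depth.z1,
                      kernel=k_dz if i > 0 else None)
    return U


def multislice_forward_backward(vol: ObjectVolume, depth: DepthGrid, grid: GridSpec,
                                g_intensity: np.ndarray | None = None,
                                hologram: np.ndarray | None = None,
                                normalize: bool = False):
    """Forward multi-slice pass plus reverse-mode gradients.

    Either supply ``hologram`` to get the MSE data-loss value and its
    gradients, or a cotangent ``g_intensity`` (dL/d-intensity) directly.
    With ``normalize`` the loss compares mean-normalized intensities,
    MSE(I/mean(I), H/mean(H)) — insensitive to the global illumination
    scale (shot-noise-limited holograms are renormalized by their
    spatial mean, so their background does not sit exactly at 1).

    Returns
    -------
    (intensity, loss, d_o_phi, d_o_A, d_phi, d_A)
        ``loss`` is None when ``g_intensity`` was supplied.  Gradient
        arrays match the occupancy shapes; ``d_phi``/``d_A`` are scalars.
    """
    cache: list = []
    U0 = _multislice_field(vol, depth, grid, cache=cache)
    intensity = np.abs(U0) ** 2
    loss = None
    if g_intensity is None:
        if hologram is None:
            raise ValueError("supply either g_intensity or hologram")
        if normalize:
            m = float(intensity.mean())
            i_norm = intensity / m
            diff = i_norm - hologram / float(np.mean(hologram))
            loss = float(np.mean(diff ** 2))
            g_norm = (2.0 / diff.size) * diff
            # adjoint of the mean-normalization I -> I/mean(I)
            g_intensity = (g_norm - np.mean(g_norm * i_norm)) / m
        else:
            diff = intensity - hologram
            loss = float(np.mean(diff ** 2))
            g_intensity = (2.0 / diff.size) * diff

    # Wirtinger cotangent with respect to conj(U_0)
    g = g_intensity * U0
    k_dz = asm_transfer(grid, depth.dz)
    d_o_phi = np.empty_like(vol.o_phi)
    d_o_A = np.empty_like(vol.o_A)
    d_phi = 0.0
    d_A = 0.0
    for i in range(depth.n_slices):
        # undo the propagation that followed slice i
        kernel = k_dz if i > 0 else asm_transfer(grid, depth.z1)
        g = _adjoint_propagate(g, kernel)
        U, V = cache[depth.n_slices - 1 - i]
        vg = V * np.conj(g)
        re, im = vg.real, vg.imag
        d_o_phi[i] = -2.0 * vol.phi * im
        d_o_A[i] = -2.0 * vol.A * re
        d_phi += -2.0 * float(np.sum(vol.o_phi[i] * im))
        d_A += -2.0 * float(np.sum(vol.o_A[i] * re))
        g = g * np.conj(transmission(vol, i))
    return intensity, loss, d_o_phi, d_o_A, d_phi, d_A


def backpropagate_to_object(intensity: np.ndarray, grid: GridSpec,
                            distance: float) -> np.ndarray:
    """Back-propagate a hologram to the object plane.

    The measured intensity is lifted to a real-amplitude, zero-phase
    detector field sqrt(H) and propagated by ``-distance``; |.|^2 of the
    result is the in-focus reconstructed hologram.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise InvalidHologramError("hologram intensities must be non-negative")
    return propagate(np.sqrt(intensity).astype(complex), grid, -distance)
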