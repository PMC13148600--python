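"""Gerchberg-Saxton iterative phase retrieval for in-line holograms.

Classic alternating projections between the detector plane (amplitude
fixed to sqrt(H)) and the object plane, where physical transmission
constraints are enforced: |t| <= 1 (no gain) and arg(t) <= 0 (phase
shift of a refractive-index decrement).  The detector field is seeded
with zero phase; the recovered maps are phase = arg(t) and absorbance
= -ln|t| after the final object-domain projection.

A single in-line hologram carries almost no low-spatial-frequency phase
contrast (the phase transfer function ~ sin(pi lambda d f^2) vanishes
at f -> 0), so the plain alternation converges to a slightly biased
fixed point.  The optional *support refinement* mode suppresses this
twin-image/nullspace residual the way the in-line holography and CDI
literature does: between rounds of GS iterations, an object support is
re-segmented from the current reconstruction (threshold on the combined
phase/absorbance magnitude, closed, filled, dilated) and the
transmission outside it is pinned to the unit background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..field import ReconstructionResult
from ..grids import GridSpec
from ..optics import InvalidHologramError, asm_transfer


@dataclass
class GSConfig:
    n_iter: int = 500
    distance: float = 100e-6  # object-detector separation (m)
    residual_tol: float = 1e-8  # early exit on residual change
    enforce_unit_amplitude: bool = True
    enforce_nonpositive_phase: bool = True
    support: np.ndarray | None = None  # fixed object support, optional
    # shrinkwrap-style support refinement (off by default)
    support_refinement: bool = False
    refine_rounds: int = 6
    refine_dilation: int = 2
    refine_threshold_frac: float = 0.2
    absorbance_weight: float = 5.0  # weight of absorbance in the support signal

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def _project_object(t: np.ndarray, cfg: GSConfig,
                    support: np.ndarray | None) -> np.ndarray:
    amp = np.abs(t)
    phase = np.angle(t)
    if cfg.enforce_unit_amplitude:
        amp = np.minimum(amp, 1.0)
    if cfg.enforce_nonpositive_phase:
        phase = np.minimum(phase, 0.0)
    t = amp * np.exp(1j * phase)
    if support is not None:
        t = np.where(support, t, 1.0 + 0j)
    return t


def _refine_support(t: np.ndarray, cfg: GSConfig) -> np.ndarray:
    mag = -np.angle(t) + cfg.absorbance_weight * (
        -np.log(np.maximum(np.abs(t), 1e-12)))
    thr = cfg.refine_threshold_frac * np.percentile(mag, 99.5)
    s = mag > thr
    s = ndimage.binary_fill_holes(ndimage.binary_closing(s, iterations=1))
    if cfg.refine_dilation:
        s = ndimage.binary_dilation(s, iterations=cfg.refine_dilation)
    return s


def gs_reconstruct(hologram: np.ndarray, grid: GridSpec,
                   cfg: GSConfig | None = None) -> ReconstructionResult:
    """Iterative reconstruction of object transmission from one hologram."""
    cfg = cfg or GSConfig()
    H = np.asarray(hologram, dtype=float)
    if np.any(H < 0):
        raise InvalidHologramError("hologram intensities must be non-negative")
    amp_det = np.sqrt(H)
    # remove the plane-wave carrier exp(+/- i 2 pi d / lambda) so the phase
    # constraint acts relative to the unscattered beam (sqrt(H) is seeded
    # with zero phase)
    k_back = asm_transfer(grid, -cfg.distance)
    k_back = k_back * np.conj(k_back[0, 0])
    k_fwd = asm_transfer(grid, cfg.distance)
    k_fwd = k_fwd * np.conj(k_fwd[0, 0])

    support = cfg.support
    rounds = cfg.refine_rounds if cfg.support_refinement else 1
    u_det = amp_det.astype(complex)
    best = (np.inf, None)
    residuals: list[float] = []
    t = u_det
    norm = np.linalg.norm(amp_det)
    for rnd in range(rounds):
        prev_res = np.inf
        for _ in range(cfg.n_iter):
            t = _project_object(
                np.fft.ifft2(np.fft.fft2(u_det) * k_back), cfg, support)
            u_sim = np.fft.ifft2(np.fft.fft2(t) * k_fwd)
            res = float(np.linalg.norm(np.abs(u_sim) - amp_det) / norm)
            residuals.append(res)
            if res < best[0]:
                best = (res, t)
            u_det = amp_det * np.exp(1j * np.angle(u_sim))
            if abs(prev_res - res) < cfg.residual_tol:
                break
            prev_res = res
        if cfg.support_refinement and rnd < rounds - 1:
            support = _refine_support(t, cfg)

    if residuals[-1] > 2 * best[0] + 1e-12:
        warnings.warn("GS residual oscillated; returning the best iterate",
                      RuntimeWarning, stacklevel=2)
        t = best[1]
    phase = np.angle(t)
    with np.errstate(divide="ignore"):
        absorbance = -np.log(np.maximum(np.abs(t), 1e-12))
    return ReconstructionResult(
        phase=phase, absorbance=absorbance, method="gerchberg-saxton",
        config={"n_iter": cfg.n_iter, "distance": cfg.distance,
                "support_refinement": cfg.support_refinement},
        epochs=len(residuals), history={"residual": residuals},
    )
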