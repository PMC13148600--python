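"""Synthetic phantoms, noise-free hologram synthesis and shot-noise simulation.

The reference phantom mirrors the benchmark object set used for
shot-noise studies of in-line X-ray holography: three weakly absorbing,
phase-shifting objects labelled alpha, beta and gamma with phase shifts
of -0.3, -0.2 and -0.1 rad and absorbances of 0.03, 0.02 and 0.01, laid
out on a 128 x 128 grid with 10 nm pixels and propagated 100 um to the
detector at a wavelength of 0.1327 nm (9.344 keV).

Glyph-shaped objects are rasterized at run time from a sans-serif font
outline; a parametric disc phantom with the same optical constants is
provided for geometry-exact oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DepthGrid, GridSpec
from .optics import propagate

#: canonical synthetic-benchmark optical constants
DEFAULT_WAVELENGTH = 0.1327e-9
DEFAULT_PIXEL = 10e-9
DEFAULT_DISTANCE = 100e-6
DEFAULT_PHASES = (-0.3, -0.2, -0.1)
DEFAULT_ABSORBANCES = (0.03, 0.02, 0.01)
OBJECT_LABELS = ("alpha", "beta", "gamma")


class PhantomSpecError(ValueError):
    """Raised for inconsistent phantom definitions (e.g. overlapping masks)."""


class InvalidMapError(ValueError):
    """Raised when phase/absorbance maps contain NaN."""


@dataclass
class PhantomObject:
    mask: np.ndarray  # binary (ny, nx)
    phase_rad: float  # <= 0 in the weak-object regime
    absorbance: float  # >= 0
    label: str


@dataclass
class PhantomSpec:
    objects: list[PhantomObject]
    grid: GridSpec
    z_prime: float = DEFAULT_DISTANCE


@dataclass
class Hologram:
    """Background-normalized intensity image with optional noise metadata."""

    intensity: np.ndarray
    mu: float | None = None
    seed: int | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("hologram intensity must be non-negative")


def disc_mask(grid: GridSpec, center: tuple[float, float], radius: float) -> np.ndarray:
    """Binary disc; center ``(row, col)`` and radius in pixels."""
    yy, xx = np.mgrid[0:grid.ny, 0:grid.nx]
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2)


def annulus_mask(grid: GridSpec, center: tuple[float, float],
                 r_outer: float, r_inner: float) -> np.ndarray:
    yy, xx = np.mgrid[0:grid.ny, 0:grid.nx]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return (r2 <= r_outer ** 2) & (r2 > r_inner ** 2)


def bar_mask(grid: GridSpec, top_left: tuple[int, int], height: int, width: int) -> np.ndarray:
    m = np.zeros(grid.shape, dtype=bool)
    r, c = top_left
    m[r:r + height, c:c + width] = True
    return m


def glyph_mask(grid: GridSpec, char: str, center: tuple[float, float],
               height_px: float) -> np.ndarray:
    """Rasterize a single character outline into a binary mask.

    Uses the bundled matplotlib sans-serif font outlines; the exact
    glyph geometry is therefore font-dependent, which is acceptable
    because all quantitative evaluation is region-mean based.
    """
    from matplotlib.font_manager import FontProperties
    from matplotlib.textpath import TextPath

    path = TextPath((0, 0), char, size=100, prop=FontProperties(family="DejaVu Sans"))
    ext = path.get_extents()
    scale = height_px / ext.height
    yy, xx = np.mgrid[0:grid.ny, 0:grid.nx]
    # map pixel coords into glyph coords (image row axis points down)
    gx = (xx - center[1]) / scale + 0.5 * (ext.x0 + ext.x1)
    gy = (center[0] - yy) / scale + 0.5 * (ext.y0 + ext.y1)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return path.contains_points(pts).reshape(grid.shape)


def default_grid(n: int = 128, pixel: float = DEFAULT_PIXEL,
                 wavelength: float = DEFAULT_WAVELENGTH) -> GridSpec:
    return GridSpec(nx=n, ny=n, dx=pixel, dy=pixel, wavelength=wavelength)


def default_depth(grid_unused: GridSpec | None = None, z_prime: float = DEFAULT_DISTANCE,
                  dz: float = 20e-9, n_slices: int = 81) -> DepthGrid:
    return DepthGrid(z_prime=z_prime, dz=dz, n_slices=n_slices)


def three_glyph_phantom(grid: GridSpec, z_prime: float = DEFAULT_DISTANCE) -> PhantomSpec:
    """The default alpha/beta/gamma glyph phantom."""
    n = min(grid.nx, grid.ny)
    h = 0.28 * n
    centers = [(0.30 * grid.ny, 0.32 * grid.nx),
               (0.38 * grid.ny, 0.68 * grid.nx),
               (0.70 * grid.ny, 0.48 * grid.nx)]
    objs = []
    for ch, ctr, ph, ab, lab in zip("αβγ", centers,
                                    DEFAULT_PHASES, DEFAULT_ABSORBANCES, OBJECT_LABELS):
        objs.append(PhantomObject(glyph_mask(grid, ch, ctr, h), ph, ab, lab))
    return PhantomSpec(objs, grid, z_prime)


def three_disc_phantom(grid: GridSpec, z_prime: float = DEFAULT_DISTANCE,
                       radius_frac: float = 0.11) -> PhantomSpec:
    """Parametric stand-in for the glyph phantom: three discs with the
    same phase/absorbance triplets, for geometry-exact tests."""
    r = radius_frac * min(grid.nx, grid.ny)
    centers = [(0.32 * grid.ny, 0.32 * grid.nx),
               (0.36 * grid.ny, 0.70 * grid.nx),
               (0.70 * grid.ny, 0.50 * grid.nx)]
    objs = [PhantomObject(disc_mask(grid, ctr, r), ph, ab, lab)
            for ctr, ph, ab, lab in zip(centers, DEFAULT_PHASES,
                                        DEFAULT_ABSORBANCES, OBJECT_LABELS)]
    return PhantomSpec(objs, grid, z_prime)


def render_phantom(spec: PhantomSpec):
    """Rasterize a phantom into reference maps and evaluation regions.

    Returns
    -------
    phase_map : (ny, nx) float array, rad
    absorbance_map : (ny, nx) float array
    regions : dict of binary masks keyed by object label, plus
        ``"background"`` and ``"entire"``.
    """
    phase = np.zeros(spec.grid.shape)
    absorb = np.zeros(spec.grid.shape)
    occupied = np.zeros(spec.grid.shape, dtype=bool)
    regions: dict[str, np.ndarray] = {}
    for obj in spec.objects:
        mask = np.asarray(obj.mask, dtype=bool)
        if mask.shape != spec.grid.shape:
            raise PhantomSpecError(f"mask for {obj.label!r} does not fit the grid")
        if np.any(mask & occupied):
            raise PhantomSpecError(f"object mask {obj.label!r} overlaps a previous one")
        occupied |= mask
        phase += obj.phase_rad * mask
        absorb += obj.absorbance * mask
        regions[obj.label] = mask
    regions["background"] = ~occupied
    regions["entire"] = np.ones(spec.grid.shape, dtype=bool)
    return phase, absorb, regions


def simulate_hologram(phase_map: np.ndarray, absorbance_map: np.ndarray,
                      distance: float, grid: GridSpec) -> Hologram:
    """Noise-free in-line hologram of a thin object at ``distance`` from
    the detector, under unit plane-wave illumination."""
    phase_map = np.asarray(phase_map, dtype=float)
    absorbance_map = np.asarray(absorbance_map, dtype=float)
    if phase_map.shape != absorbance_map.shape:
        raise ValueError("phase and absorbance maps must share a shape")
    if np.any(~np.isfinite(phase_map)) or np.any(~np.isfinite(absorbance_map)):
        raise InvalidMapError("maps contain NaN/Inf")
    if distance <= 0:
        raise ValueError("object-detector distance must be positive")
    u_obj = np.exp(1j * phase_map - absorbance_map)
    u_det = propagate(u_obj, grid, distance)
    return Hologram(np.abs(u_det) ** 2, provenance="noise-free")


def apply_shot_noise(holo: Hologram, mu: float, seed: int) -> Hologram:
    """Shot-noise-limited hologram at mean photon count ``mu`` per pixel.

    Per pixel the expected count is ``lam = mu * H / mean(H)``; a Poisson
    count is drawn and rescaled by ``1/mu`` back to the normalized
    intensity scale.  Draws are made in row-major order from a seeded
    ``numpy.random.Generator`` so results are bit-reproducible.
    """
    if mu <= 0:
        raise ValueError("mean photon count mu must be positive")
    H = holo.intensity
    lam = mu * H / H.mean()
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam)
    return Hologram(counts / mu, mu=mu, seed=seed,
                    provenance=f"SNL mu={mu} seed={seed}")
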