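"""YAML configuration loading and validation."""

from __future__ import annotations

from pathlib import Path

import yaml

from .grids import DepthGrid, GridSpec


class ConfigError(ValueError):
    pass


OPTICS_KEYS = ("wavelength_m", "dx_m", "dy_m", "dz_m", "z_prime_m", "n_slices")


def load_optics(path: str | Path) -> tuple[GridSpec, DepthGrid]:
    """Load an optics block: wavelength, pixel pitch, depth grid, medium.

    Required keys: wavelength_m, dx_m, dy_m, dz_m, z_prime_m, n_slices,
    plus the grid size nx/ny.  Optional: n_med (default 1).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("optics config must be a mapping")
    block = raw.get("optics", raw)
    missing = [k for k in OPTICS_KEYS + ("nx", "ny") if k not in block]
    if missing:
        raise ConfigError(f"optics config missing keys: {missing}")
    try:
        grid = GridSpec(nx=int(block["nx"]), ny=int(block["ny"]),
                        dx=float(block["dx_m"]), dy=float(block["dy_m"]),
                        wavelength=float(block["wavelength_m"]),
                        n_med=float(block.get("n_med", 1.0)))
        depth = DepthGrid(z_prime=float(block["z_prime_m"]),
                          dz=float(block["dz_m"]),
                          n_slices=int(block["n_slices"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid optics config: {exc}") from exc
    return grid, depth


def default_optics_dict(grid: GridSpec, depth: DepthGrid) -> dict:
    return {"optics": {
        "wavelength_m": grid.wavelength, "dx_m": grid.dx, "dy_m": grid.dy,
        "dz_m": depth.dz, "z_prime_m": depth.z_prime,
        "n_slices": depth.n_slices, "n_med": grid.n_med,
        "nx": grid.nx, "ny": grid.ny,
    }}
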