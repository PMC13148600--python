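"""Hologram and map file I/O.

Intensity and map images travel as single-page 32-bit float TIFF
(row-major, origin top-left) or NPY; complex fields as paired
real/imag NPY.  Every written artifact gets a JSON sidecar carrying its
provenance (noise level, seed, optics block).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .phantom import Hologram

SIDECAR_REQUIRED = ("kind",)


class FormatError(ValueError):
    pass


class SidecarSchemaError(ValueError):
    pass


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D float image from TIFF or NPY.

    Integer TIFF inputs are promoted to float (values preserved; the
    original dtype is not retained).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        arr = np.load(path)
    else:
        raise FormatError(f"unknown image extension: {path.suffix!r}")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D image, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_image(path: str | Path, data: np.ndarray) -> None:
    path = Path(path)
    data = np.asarray(data)
    if data.ndim != 2:
        raise FormatError("only 2-D images are written")
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data.astype(np.float32))
    elif path.suffix.lower() == ".npy":
        np.save(path, data)
    else:
        raise FormatError(f"unknown image extension: {path.suffix!r}")


def write_complex(path_stem: str | Path, field: np.ndarray) -> tuple[Path, Path]:
    """Store a complex field as <stem>.real.npy / <stem>.imag.npy."""
    stem = Path(path_stem)
    pr = stem.with_suffix(".real.npy")
    pi = stem.with_suffix(".imag.npy")
    np.save(pr, np.real(field))
    np.save(pi, np.imag(field))
    return pr, pi


def read_complex(path_stem: str | Path) -> np.ndarray:
    stem = Path(path_stem)
    return (np.load(stem.with_suffix(".real.npy"))
            + 1j * np.load(stem.with_suffix(".imag.npy")))


def write_sidecar(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_sidecar(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    for key in SIDECAR_REQUIRED:
        if key not in payload:
            raise SidecarSchemaError(f"sidecar missing required key {key!r}")
    return payload


def write_hologram(path: str | Path, holo: Hologram, extra: dict | None = None) -> None:
    path = Path(path)
    write_image(path, holo.intensity)
    payload = {"kind": "hologram", "mu": holo.mu, "seed": holo.seed,
               "provenance": holo.provenance,
               "spatial_mean": float(holo.intensity.mean())}
    payload.update(extra or {})
    write_sidecar(path.with_suffix(path.suffix + ".json"), payload)


def read_hologram(path: str | Path) -> Hologram:
    path = Path(path)
    intensity = read_image(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    mu = seed = None
    provenance = ""
    if sidecar.exists():
        meta = read_sidecar(sidecar)
        mu, seed = meta.get("mu"), meta.get("seed")
        provenance = meta.get("provenance", "")
    return Hologram(intensity, mu=mu, seed=seed, provenance=provenance)
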