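"""Coordinate neural field for single-shot phase/absorbance retrieval.

The reconstructor is a small coordinate MLP ("neural field") that maps
a normalized voxel coordinate (x, y, z) in [0, 1]^3 to two occupancy
values (o_phi, o_A) in (0, 1).  Training has two stages:

1. *Pre-training* drives the field toward a candidate object region: an
   MSE loss against a stack of binary object-mask labels replicated on
   the slices around the approximate depth z' (labels are zero
   elsewhere).
2. *Physics training* propagates a unit beam through the materialized
   occupancy volume with the multi-slice angular-spectrum forward model
   and minimizes the MSE between the simulated detector intensity and
   the measured hologram, plus boundary-condition losses pinning the
   occupancy to zero on the six faces of the volume.

Both stages use Adam on the full coordinate lattice each epoch (the
forward model couples every voxel to every detector pixel, so pixelwise
mini-batching has no physical meaning).  All gradients are computed by
the explicit reverse-mode passes in :mod:`holofield.nn` and
:mod:`holofield.optics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .grids import DepthGrid, GridSpec
from .masks import MaskLabelStack
from .nn import Adam, Dense
from .optics import ObjectVolume, multislice_forward_backward


class TrainingError(RuntimeError):
    """Raised when a loss turns NaN/Inf during optimization."""


@dataclass
class TrainConfig:
    """Hyperparameters of the two-stage optimization.

    Reference-scale defaults: 300 pre-training epochs at lr 1e-3 and
    3000 physics epochs at lr 1e-4 (synthetic holograms; experimental
    holograms use 2000 epochs at lr 1e-5 with trainable coefficients).
    """

    pretrain_epochs: int = 300
    pretrain_lr: float = 1e-3
    train_epochs: int = 3000
    train_lr: float = 1e-4
    seed: int = 0
    trainable_coeffs: bool = False
    coeff_lr: Optional[float] = None  # defaults to train_lr
    early_stop_patience: Optional[int] = 200  # epochs on smoothed data loss
    smooth_window: int = 10
    #: discrepancy-principle stop: halt once the smoothed data loss falls
    #: below this absolute level (the expected shot-noise variance floor of
    #: the hologram); None disables it
    noise_floor: Optional[float] = None
    #: compare mean-normalized intensities in the data loss,
    #: MSE(I/mean(I), H/mean(H)).  The shot-noise model rescales the
    #: hologram by its spatial mean, so a noisy hologram's background sits
    #: at 1/mean(H) > 1; fitting it with a unit-illumination model absorbs
    #: that offset as a systematic absorbance deficit unless the loss is
    #: made insensitive to the global illumination scale
    normalize_data: bool = False

    def __post_init__(self) -> None:
        if self.pretrain_epochs < 1 or self.train_epochs < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.pretrain_lr <= 0 or self.train_lr <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class ReconstructionResult:
    phase: np.ndarray
    absorbance: np.ndarray
    method: str
    config: dict = dc_field(default_factory=dict)
    epochs: int = 0
    history: dict = dc_field(default_factory=dict)


class FieldNetwork:
    """Fourier-feature MLP: 3 coords -> 128 features -> 3 x Dense(128, swish)
    -> Dense(2, sigmoid).

    The positional encoding follows the random-Fourier-features recipe:
    a fixed Gaussian matrix B (64 x 3, entries ~ N(0, sigma^2)) maps the
    coordinate c to [sin(2 pi B c), cos(2 pi B c)].  ``gaussian_scale``
    sigma controls the bandwidth (15 for the synthetic default, 25 for
    experimental holograms).
    """

    N_FOURIER = 64
    HIDDEN = (128, 128, 128)

    def __init__(self, seed: int = 0, gaussian_scale: float = 15.0,
                 dtype=np.float32):
        self.seed = seed
        self.gaussian_scale = float(gaussian_scale)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.B = (gaussian_scale * rng.standard_normal((3, self.N_FOURIER))).astype(dtype)
        width = 2 * self.N_FOURIER
        self.layers = []
        n_in = width
        for i, h in enumerate(self.HIDDEN):
            self.layers.append(Dense(rng, n_in, h, activation="swish", dtype=dtype,
                                     needs_input_grad=i > 0))
            n_in = h
        self.layers.append(Dense(rng, n_in, 2, activation="sigmoid", dtype=dtype))

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def save(self, path) -> None:
        arrays = {"B": self.B, "seed": np.array(self.seed),
                  "gaussian_scale": np.array(self.gaussian_scale)}
        for i, layer in enumerate(self.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "FieldNetwork":
        data = np.load(path)
        net = cls(seed=int(data["seed"]), gaussian_scale=float(data["gaussian_scale"]))
        net.B = data["B"]
        for i, layer in enumerate(net.layers):
            layer.W[...] = data[f"W{i}"]
            layer.b[...] = data[f"b{i}"]
        return net

    # -- forward / backward -------------------------------------------------
    def encode(self, coords: np.ndarray) -> np.ndarray:
        """Fourier positional encoding of an (P, 3) coordinate batch."""
        proj = 2.0 * np.pi * coords.astype(self.dtype) @ self.B
        return np.concatenate([np.sin(proj), np.cos(proj)], axis=1)

    def forward(self, coords: np.ndarray) -> np.ndarray:
        return self.forward_encoded(self.encode(coords))

    def forward_encoded(self, features: np.ndarray) -> np.ndarray:
        """Forward pass from precomputed Fourier features (the encoding of
        a fixed lattice can be cached across epochs)."""
        x = features
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, d_out: np.ndarray) -> None:
        g = d_out.astype(self.dtype)
        for layer in reversed(self.layers):
            g = layer.backward(g)


def lattice_coords(grid: GridSpec, depth: DepthGrid) -> np.ndarray:
    """Normalized (P, 3) coordinates of the full L x M x N lattice.

    In-plane coordinates are x/(L dx) and y/(M dy) with x = (l+1) dx,
    so they lie in (0, 1]; the axial coordinate is affinely mapped from
    [z_1, z_N] onto [0, 1].  The flattened order matches a volume of
    shape (n_slices, ny, nx).
    """
    x = (np.arange(grid.nx) + 1.0) / grid.nx
    y = (np.arange(grid.ny) + 1.0) / grid.ny
    z = (np.arange(depth.n_slices) / max(depth.n_slices - 1, 1))
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])


def _as_volumes(o: np.ndarray, grid: GridSpec, depth: DepthGrid):
    shape = (depth.n_slices, grid.ny, grid.nx)
    return o[:, 0].reshape(shape), o[:, 1].reshape(shape)


def materialize_volume(net: FieldNetwork, grid: GridSpec, depth: DepthGrid,
                       phi: float, A: float) -> ObjectVolume:
    o = net.forward(lattice_coords(grid, depth)).astype(np.float64)
    o_phi, o_A = _as_volumes(o, grid, depth)
    return ObjectVolume(o_phi, o_A, phi, A)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def loss_prior(o: np.ndarray, label_volume: np.ndarray,
               with_grad: bool = False):
    """MSE of both occupancy channels against the label volume.

    ``o`` is the (P, 2) network output over the full lattice; the label
    volume (n_slices, ny, nx) applies to both channels.
    """
    labels = label_volume.reshape(-1, 1)
    if labels.shape[0] != o.shape[0]:
        raise ValueError("label volume does not match the coordinate lattice")
    diff = o.astype(np.float64) - labels
    loss = float(np.mean(diff ** 2))
    if not with_grad:
        return loss
    return loss, (2.0 / diff.size) * diff


def _face_index_sets(grid: GridSpec, depth: DepthGrid):
    n, ny, nx = depth.n_slices, grid.ny, grid.nx
    vol_idx = np.arange(n * ny * nx).reshape(n, ny, nx)
    return (
        np.concatenate([vol_idx[:, :, 0].ravel(), vol_idx[:, :, -1].ravel()]),
        np.concatenate([vol_idx[:, 0, :].ravel(), vol_idx[:, -1, :].ravel()]),
        np.concatenate([vol_idx[0].ravel(), vol_idx[-1].ravel()]),
    )


def loss_boundary(o: np.ndarray, grid: GridSpec, depth: DepthGrid,
                  with_grad: bool = False):
    """Sum of the x-, y- and z-face boundary losses.

    Each term is the MSE of both channels against zero over the
    corresponding pair of volume faces (first/last column, row, slice).
    """
    o64 = o.astype(np.float64)
    total = 0.0
    grad = np.zeros_like(o64) if with_grad else None
    for idx in _face_index_sets(grid, depth):
        vals = o64[idx]
        total += float(np.mean(vals ** 2))
        if with_grad:
            np.add.at(grad, idx, (2.0 / vals.size) * vals)
    return (total, grad) if with_grad else total


def loss_data(net: FieldNetwork, phi: float, A: float, hologram: np.ndarray,
              depth: DepthGrid, grid: GridSpec) -> float:
    """MSE between the simulated detector intensity and the hologram."""
    vol = materialize_volume(net, grid, depth, phi, A)
    _, loss, *_ = multislice_forward_backward(vol, depth, grid, hologram=hologram)
    return loss


def data_loss_and_param_grads(net: FieldNetwork, phi: float, A: float,
                              hologram: np.ndarray, depth: DepthGrid,
                              grid: GridSpec):
    """Data loss plus gradients w.r.t. every network weight and (phi, A).

    One full forward/reverse sweep: lattice -> MLP -> occupancy volume
    -> multi-slice propagation -> intensity MSE, then the adjoint chain
    back through the optics into the MLP.
    """
    coords = lattice_coords(grid, depth)
    o = net.forward(coords)
    o_phi, o_A = _as_volumes(o.astype(np.float64), grid, depth)
    vol = ObjectVolume(o_phi, o_A, phi, A)
    _, loss, d_ophi, d_oA, d_phi, d_A = multislice_forward_backward(
        vol, depth, grid, hologram=hologram)
    d_o = np.column_stack([d_ophi.ravel(), d_oA.ravel()])
    net.zero_grad()
    net.backward(d_o)
    return loss, net.grads(), d_phi, d_A


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _check_finite(loss: float, stage: str, epoch: int) -> None:
    if not np.isfinite(loss):
        raise TrainingError(f"{stage} loss diverged (NaN/Inf) at epoch {epoch}")


def pretrain(net: FieldNetwork, labels: MaskLabelStack, grid: GridSpec,
             cfg: TrainConfig) -> list[float]:
    """Stage 1: fit the field to the mask label stack; returns the loss log."""
    features = net.encode(lattice_coords(grid, labels.depth))
    label_vol = labels.label_volume()
    opt = Adam(net.params, lr=cfg.pretrain_lr)
    history: list[float] = []
    for epoch in range(cfg.pretrain_epochs):
        o = net.forward_encoded(features)
        loss, d_o = loss_prior(o, label_vol, with_grad=True)
        _check_finite(loss, "pre-training", epoch)
        net.zero_grad()
        net.backward(d_o)
        opt.step(net.grads())
        history.append(loss)
    return history


def train(net: FieldNetwork, hologram: np.ndarray, depth: DepthGrid,
          grid: GridSpec, cfg: TrainConfig, phi: float, A: float,
          w_z: int | None = None) -> ReconstructionResult:
    """Stage 2: minimize L_data + L_bc; returns maps extracted over the
    axial window (defaults to the pre-training window when ``w_z`` given,
    otherwise the full depth range)."""
    if hologram.shape != grid.shape:
        raise ValueError("hologram shape does not match the grid")
    features = net.encode(lattice_coords(grid, depth))
    opt = Adam(net.params, lr=cfg.train_lr)
    phi = float(phi)
    A = float(A)
    coeff_opt = None
    if cfg.trainable_coeffs:
        self_coeffs = [np.array(phi), np.array(A)]
        coeff_opt = Adam(self_coeffs, lr=cfg.coeff_lr or cfg.train_lr)
    hist_data: list[float] = []
    hist_bc: list[float] = []
    best = np.inf
    stall = 0
    for epoch in range(cfg.train_epochs):
        o = net.forward_encoded(features)
        o_phi, o_A = _as_volumes(o.astype(np.float64), grid, depth)
        vol = ObjectVolume(o_phi, o_A, phi, A)
        _, l_data, d_ophi, d_oA, d_phi, d_A = multislice_forward_backward(
            vol, depth, grid, hologram=hologram, normalize=cfg.normalize_data)
        l_bc, d_bc = loss_boundary(o, grid, depth, with_grad=True)
        _check_finite(l_data + l_bc, "training", epoch)
        d_o = np.column_stack([d_ophi.ravel(), d_oA.ravel()]) + d_bc
        net.zero_grad()
        net.backward(d_o)
        opt.step(net.grads())
        if coeff_opt is not None:
            coeff_opt.step([np.array(d_phi), np.array(d_A)])
            phi = float(self_coeffs[0])
            A = float(max(self_coeffs[1], 0.0))
            self_coeffs[1][...] = A
        hist_data.append(l_data)
        hist_bc.append(l_bc)
        # early stopping: (a) discrepancy principle — once the data loss
        # reaches the shot-noise variance floor, further fitting only
        # absorbs noise; (b) patience on a smoothed plateau
        if len(hist_data) >= cfg.smooth_window:
            smoothed = float(np.mean(hist_data[-cfg.smooth_window:]))
            if cfg.noise_floor is not None and smoothed < cfg.noise_floor:
                break
            if cfg.early_stop_patience is not None:
                if smoothed < best * (1.0 - 1e-5):
                    best = smoothed
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.early_stop_patience:
                        break
    window = depth.window_indices(w_z) if w_z is not None else None
    phase_map, absorb_map = extract_maps(net, phi, A, grid, depth, window)
    return ReconstructionResult(
        phase=phase_map, absorbance=absorb_map, method="neural-field",
        config={"phi": phi, "A": A, "train_lr": cfg.train_lr, "seed": cfg.seed,
                "trainable_coeffs": cfg.trainable_coeffs,
                "normalize_data": cfg.normalize_data},
        epochs=len(hist_data),
        history={"data": hist_data, "bc": hist_bc},
    )


def extract_maps(net: FieldNetwork, phi: float, A: float, grid: GridSpec,
                 depth: DepthGrid, window: np.ndarray | None = None):
    """Collapse the occupancy volume near the object plane into 2-D maps.

    The phase map is phi * sum_i o_phi[i] over the window slices (and
    likewise for absorbance), so a one-slice-thick object reproduces its
    coefficient exactly and thicker occupancy accumulates.
    """
    vol = materialize_volume(net, grid, depth, phi, A)
    if window is None:
        window = np.arange(depth.n_slices)
    phase = phi * vol.o_phi[window].sum(axis=0)
    absorb = A * vol.o_A[window].sum(axis=0)
    return phase, absorb
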