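"""Self-supervised residual U-Net baseline for hologram inversion.

An encoder-decoder with three downsampling stages, symmetric
upsampling, skip connections and swish activations maps the hologram
directly to object-plane maps.  The phase head (1x1 convolution +
sigmoid) is scaled to the expected maximum phase magnitude; the
absorbance head feeds the predicted phase map through one extra
residual block and a 1x1 convolution with leaky-ReLU, scaled likewise.
Both maps are forward-propagated to the detector with the same
angular-spectrum operator used everywhere else in the package, and the
MSE against the input hologram is minimized — no training dataset is
involved, only the single hologram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..field import ReconstructionResult, TrainingError
from ..grids import GridSpec
from ..nn import Adam, AvgPool2, Conv2d, UpsampleNearest2, swish, swish_grad
from ..optics import asm_transfer


@dataclass
class ResUNetConfig:
    widths: tuple[int, int, int] = (32, 64, 128)
    phase_scale: float = 0.3       # max |phase| in rad (0.278 experimental)
    absorb_scale: float = 0.03     # max absorbance (0.1 experimental)
    epochs: int = 30000
    lr: float = 1e-6
    seed: int = 0
    dtype: type = np.float32

    def __post_init__(self) -> None:
        if self.phase_scale <= 0 or self.absorb_scale <= 0:
            raise ValueError("output scales must be positive")


class _ResBlock:
    """conv-swish-conv + (projected) skip, swish after the addition."""

    def __init__(self, rng, c_in: int, c_out: int, dtype):
        self.conv1 = Conv2d(rng, c_in, c_out, 3, activation="swish", dtype=dtype)
        self.conv2 = Conv2d(rng, c_out, c_out, 3, activation=None, dtype=dtype)
        self.proj = Conv2d(rng, c_in, c_out, 1, activation=None, dtype=dtype) \
            if c_in != c_out else None
        self.layers = [self.conv1, self.conv2] + ([self.proj] if self.proj else [])

    def forward(self, x):
        y = self.conv2.forward(self.conv1.forward(x))
        s = self.proj.forward(x) if self.proj else x
        self._z = y + s
        return swish(self._z)

    def backward(self, g):
        g = g * swish_grad(self._z)
        gx = self.proj.backward(g) if self.proj else g
        return self.conv1.backward(self.conv2.backward(g)) + gx


class ResUNet:
    def __init__(self, cfg: ResUNetConfig):
        rng = np.random.default_rng(cfg.seed)
        w0, w1, w2 = cfg.widths
        dt = cfg.dtype
        self.stem = Conv2d(rng, 1, w0, 3, activation="swish", dtype=dt)
        self.enc = [_ResBlock(rng, w0, w0, dt), _ResBlock(rng, w0, w1, dt),
                    _ResBlock(rng, w1, w2, dt)]
        self.pools = [AvgPool2() for _ in range(3)]
        self.bottleneck = _ResBlock(rng, w2, w2, dt)
        self.ups = [UpsampleNearest2() for _ in range(3)]
        self.dec = [_ResBlock(rng, w2 + w2, w1, dt), _ResBlock(rng, w1 + w1, w0, dt),
                    _ResBlock(rng, w0 + w0, w0, dt)]
        self.phase_head = Conv2d(rng, w0, 1, 1, activation="sigmoid", dtype=dt)
        self.absorb_block = _ResBlock(rng, 1, w0, dt)
        self.absorb_head = Conv2d(rng, w0, 1, 1, activation="leaky_relu", dtype=dt)
        self.cfg = cfg
        self._blocks = ([self.stem] + self.enc + [self.bottleneck] + self.dec
                        + [self.phase_head, self.absorb_block, self.absorb_head])

    @property
    def params(self):
        out = []
        for blk in self._blocks:
            layers = blk.layers if isinstance(blk, _ResBlock) else [blk]
            for l in layers:
                out.extend(l.params)
        return out

    def grads(self):
        out = []
        for blk in self._blocks:
            layers = blk.layers if isinstance(blk, _ResBlock) else [blk]
            for l in layers:
                out.extend(l.grads)
        return out

    def zero_grad(self):
        for g in self.grads():
            g[...] = 0.0

    def forward(self, x: np.ndarray):
        """x: (1, 1, ny, nx) -> (phase_mag, absorbance) maps (ny, nx)."""
        h = self.stem.forward(x)
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            h = enc.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            h = dec.forward(np.concatenate([h, skip], axis=1))
        self._nskip = [s.shape[1] for s in skips]
        p = self.phase_head.forward(h) * self.cfg.phase_scale
        a = self.absorb_head.forward(self.absorb_block.forward(p)) * self.cfg.absorb_scale
        return p[0, 0], a[0, 0]

    def backward(self, g_phase: np.ndarray, g_absorb: np.ndarray):
        ga = (g_absorb[None, None] * self.cfg.absorb_scale)
        gp_from_a = self.absorb_block.backward(self.absorb_head.backward(ga))
        gp = g_phase[None, None] + gp_from_a
        g = self.phase_head.backward(gp * self.cfg.phase_scale)
        pending_skips = []
        for up, dec, nskip in zip(reversed(self.ups), reversed(self.dec),
                                  self._nskip):
            g = dec.backward(g)
            g_up = g[:, :g.shape[1] - nskip]
            # skip-path gradient rejoins the encoder stream below
            g_skip = g[:, g.shape[1] - nskip:]
            g = up.backward(g_up)
            pending_skips.append(g_skip)
        # pending_skips arrived shallow-to-deep encoder order; the encoder
        # backward walks deep-to-shallow
        pend = list(reversed(pending_skips))
        g = self.bottleneck.backward(g)
        for enc, pool, g_skip in zip(reversed(self.enc), reversed(self.pools),
                                     pend):
            g = pool.backward(g) + g_skip
            g = enc.backward(g)
        self.stem.backward(g)


def resunet_train_reconstruct(hologram: np.ndarray, grid: GridSpec,
                              distance: float,
                              cfg: ResUNetConfig | None = None) -> ReconstructionResult:
    """Train the U-Net on one hologram and return the recovered maps.

    The phase head produces the phase *magnitude*; the physical
    (negative) sign is applied inside the forward model and in the
    returned phase map.
    """
    cfg = cfg or ResUNetConfig()
    H = np.asarray(hologram, dtype=float)
    if H.shape != grid.shape:
        raise ValueError("hologram shape does not match grid")
    if H.shape[0] % 8 or H.shape[1] % 8:
        raise ValueError("grid dimensions must be divisible by 8")
    net = ResUNet(cfg)
    opt = Adam(net.params, lr=cfg.lr)
    x = H[None, None].astype(cfg.dtype)
    k_fwd = asm_transfer(grid, distance)
    k_adj = np.conj(k_fwd)
    losses: list[float] = []
    p = a = None
    for epoch in range(cfg.epochs):
        p, a = net.forward(x)
        t = np.exp(-1j * p.astype(np.float64) - a.astype(np.float64))
        u = np.fft.ifft2(np.fft.fft2(t) * k_fwd)
        intensity = np.abs(u) ** 2
        diff = intensity - H
        loss = float(np.mean(diff ** 2))
        if not np.isfinite(loss):
            raise TrainingError(f"ResUNet loss diverged at epoch {epoch}")
        losses.append(loss)
        gbar_u = (2.0 / diff.size) * diff * u
        gbar_t = np.fft.ifft2(np.fft.fft2(gbar_u) * k_adj)
        w = t * np.conj(gbar_t)
        g_phase = 2.0 * w.imag   # d/dp of 2 Re[conj(g) (-i t)]
        g_absorb = -2.0 * w.real
        net.zero_grad()
        net.backward(g_phase.astype(cfg.dtype), g_absorb.astype(cfg.dtype))
        opt.step(net.grads())
    return ReconstructionResult(
        phase=-p.astype(np.float64), absorbance=a.astype(np.float64),
        method="resunet",
        config={"epochs": cfg.epochs, "lr": cfg.lr, "widths": cfg.widths,
                "phase_scale": cfg.phase_scale, "absorb_scale": cfg.absorb_scale,
                "seed": cfg.seed},
        epochs=len(losses), history={"data": losses},
    )
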