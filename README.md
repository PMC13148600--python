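# holofield

Physics-driven neural-field retrieval of **phase and absorbance maps
from a single shot-noise-limited in-line X-ray hologram**.

In-line holographic microscopy records one intensity image — the
interference between the unscattered beam and the wave scattered by a
weakly refracting object.  Under weak illumination (mean photon counts
μ of order 100–1000 per pixel) Poisson shot noise dominates, and
classical iterative phase retrieval degrades badly.  `holofield`
reconstructs the object by optimizing a *neural field*: a coordinate
MLP that maps a voxel position to two occupancies (o_φ, o_A) ∈ (0,1),
trained so that a unit beam propagated through the predicted volume
with the multi-slice angular-spectrum model reproduces the measured
hologram,

    L = MSE(|U₀|², H) + L_boundary ,   U₀ = ASM-multislice(o_φ, o_A; φ, A),

after pre-training the field toward a rough object mask segmented from
the back-propagated hologram.  The per-voxel coefficients φ (rad) and
A relate to the complex refractive index n = 1 − δ + iκ via
φ = −2πδt/λ and A = 2πκt/λ.  Gerchberg–Saxton (GS) and self-supervised
ResUNet baselines, a phantom/shot-noise simulator and a region-based
evaluation harness (means, MAE, SSIM, percentage errors) are included.
Everything — including reverse-mode gradients through the FFT optics —
is implemented on numpy/scipy; see `docs/methods.md` for the model
details and design choices.

## Worked example

Reconstruct a shot-noise-limited hologram of the default three-object
phantom (phase shifts −0.3/−0.2/−0.1 rad, absorbances 0.03/0.02/0.01)
at desk scale:

```python
import numpy as np
from holofield import (DepthGrid, GridSpec, apply_shot_noise,
                       render_phantom, simulate_hologram, three_disc_phantom)
from holofield.field import TrainConfig
from holofield.metrics import average_percentage_error
from holofield.pipeline import reconstruct_neural_field

grid = GridSpec(48, 48, dx=20e-9, dy=20e-9, wavelength=0.1327e-9)
depth = DepthGrid(z_prime=100e-6, dz=20e-9, n_slices=13)
phase, absorb, regions = render_phantom(three_disc_phantom(grid))
# mu = 1000 photons per reference 10 nm pixel -> 4000 per 20 nm pixel
hologram = apply_shot_noise(
    simulate_hologram(phase, absorb, depth.z_prime, grid), mu=4000, seed=0)

cfg = TrainConfig(pretrain_epochs=40, train_epochs=450, train_lr=1e-3,
                  early_stop_patience=None)
result = reconstruct_neural_field(hologram.intensity, grid, depth,
                                  phi=-0.3, A=0.03, cfg=cfg,
                                  gaussian_scale=6.0, mu=4000)

err_phase = average_percentage_error(
    result.phase, regions, {"alpha": -0.3, "beta": -0.2, "gamma": -0.1})
err_abs = average_percentage_error(
    result.absorbance, regions, {"alpha": 0.03, "beta": 0.02, "gamma": 0.01})
print(f"epochs run: {result.epochs}")
print(f"average phase error:      {err_phase:.2f} %")
print(f"average absorbance error: {err_abs:.2f} %")
```

Output (one CPU core, a couple of minutes):

```
epochs run: 366
average phase error:      4.39 %
average absorbance error: 11.97 %
```

The training stopped itself at epoch 366, where the data loss reached
the shot-noise floor of the hologram.  The phase map's object-region
means land within ~4% of the true −0.3/−0.2/−0.1 rad and the absorbance
means within ~12% of 0.03/0.02/0.01 — both far better than the GS
baseline on the same hologram (tens of percent; compare
`gs_reconstruct`).

A CLI mirrors the library (`holofield simulate|mask|pretrain|train|gs|
resunet|evaluate|benchmark`, see `--help`).

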