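"""Neural field: encoding, losses, gradients and the training loops."""

import numpy as np
import pytest

from holofield import DepthGrid, GridSpec, build_label_stack
from holofield.field import FieldNetwork, TrainConfig, \
    data_loss_and_param_grads, lattice_coords, loss_boundary, loss_prior, \
    materialize_volume, pretrain, train
from holofield.masks import MaskLabelStack
from holofield.phantom import disc_mask, render_phantom, simulate_hologram, \
    three_disc_phantom


@pytest.fixture()
def tiny():
    grid = GridSpec(16, 16, 20e-9, 20e-9, 0.1327e-9)
    depth = DepthGrid(100e-6, 20e-9, 11)
    return grid, depth


class TestEncoding:
    def test_zero_coordinate_encodes_to_sin0_cos1(self):
        net = FieldNetwork(seed=0)
        feat = net.encode(np.zeros((1, 3)))
        assert feat.shape == (1, 128)
        assert np.allclose(feat[0, :64], 0.0)
        assert np.allclose(feat[0, 64:], 1.0)

    def test_feature_width_is_128(self):
        net = FieldNetwork(seed=1)
        feat = net.encode(np.random.default_rng(0).random((10, 3)))
        assert feat.shape == (10, 128)

    @pytest.mark.parametrize("scale", [15.0, 25.0])
    def test_projection_rows_scale_with_sigma(self, scale):
        """Entries of the random projection are N(0, sigma^2): the RMS entry
        magnitude scales linearly with the Gaussian scale."""
        net = FieldNetwork(seed=0, gaussian_scale=scale)
        rms = np.sqrt(np.mean(net.B.astype(np.float64) ** 2))
        assert rms == pytest.approx(scale, rel=0.15)

    def test_lattice_coords_normalized(self, tiny):
        grid, depth = tiny
        c = lattice_coords(grid, depth)
        assert c.shape == (depth.n_slices * 16 * 16, 3)
        assert c.min() >= 0.0 and c.max() <= 1.0


class TestForward:
    def test_outputs_bounded_in_unit_interval(self):
        net = FieldNetwork(seed=0)
        coords = np.random.default_rng(0).random((10_000, 3))
        o = net.forward(coords)
        assert o.shape == (10_000, 2)
        assert np.all((o > 0) & (o < 1))

    def test_same_seed_gives_identical_network(self):
        coords = np.random.default_rng(0).random((100, 3))
        a = FieldNetwork(seed=7).forward(coords)
        b = FieldNetwork(seed=7).forward(coords)
        assert np.array_equal(a, b)
        c = FieldNetwork(seed=8).forward(coords)
        assert not np.array_equal(a, c)

    def test_save_load_round_trip(self, tmp_path):
        net = FieldNetwork(seed=3, gaussian_scale=25.0)
        coords = np.random.default_rng(0).random((50, 3))
        net.save(tmp_path / "net.npz")
        again = FieldNetwork.load(tmp_path / "net.npz")
        assert np.array_equal(net.forward(coords), again.forward(coords))


class TestLossPrior:
    def test_exact_match_gives_zero(self, tiny):
        grid, depth = tiny
        labels = np.zeros((depth.n_slices, 16, 16))
        o = np.zeros((labels.size, 2))
        assert loss_prior(o, labels) == 0.0

    def test_half_output_on_binary_labels(self, tiny):
        grid, depth = tiny
        labels = np.zeros((depth.n_slices, 16, 16))
        labels[5, 4:8, 4:8] = 1.0
        o = np.full((labels.size, 2), 0.5)
        frac = labels.mean()
        want = (1 - frac) * 0.25 + frac * 0.25
        assert loss_prior(o, labels) == pytest.approx(want, abs=1e-12)

    def test_matches_brute_force_quadruple_sum(self):
        """Explicit loop over (slice, row, col, channel) on an 8x8x5 toy."""
        rng = np.random.default_rng(5)
        labels = (rng.random((5, 8, 8)) > 0.5).astype(float)
        o = rng.random((5 * 8 * 8, 2))
        got = loss_prior(o, labels)
        total = 0.0
        ov = o.reshape(5, 8, 8, 2)
        for i in range(5):
            for r in range(8):
                for c in range(8):
                    for ch in range(2):
                        total += (ov[i, r, c, ch] - labels[i, r, c]) ** 2
        assert got == pytest.approx(total / (5 * 8 * 8 * 2), abs=1e-12)

    def test_gradient_is_mse_derivative(self, tiny):
        grid, depth = tiny
        rng = np.random.default_rng(0)
        labels = (rng.random((depth.n_slices, 16, 16)) > 0.7).astype(float)
        o = rng.random((labels.size, 2))
        loss, g = loss_prior(o, labels, with_grad=True)
        eps = 1e-7
        o2 = o.copy()
        o2[123, 1] += eps
        fd = (loss_prior(o2, labels) - loss) / eps
        assert fd == pytest.approx(g[123, 1], rel=1e-4)


class TestLossBoundary:
    def test_zero_on_faces_gives_zero(self, tiny):
        grid, depth = tiny
        o = np.zeros((depth.n_slices * 256, 2))
        assert loss_boundary(o, grid, depth) == 0.0

    def test_unit_output_gives_three(self, tiny):
        grid, depth = tiny
        o = np.ones((depth.n_slices * 256, 2))
        assert loss_boundary(o, grid, depth) == pytest.approx(3.0)

    def test_matches_brute_force_face_enumeration(self):
        """Explicit face sums on a 6x6x4... (4 slices would be even; use 5)."""
        grid = GridSpec(6, 6, 20e-9, 20e-9, 0.1327e-9)
        depth = DepthGrid(100e-6, 20e-9, 5)
        rng = np.random.default_rng(2)
        o = rng.random((5 * 36, 2))
        got = loss_boundary(o, grid, depth)
        ov = o.reshape(5, 6, 6, 2)
        terms = []
        for axis_vals in [(ov[:, :, 0], ov[:, :, -1]),     # x faces
                          (ov[:, 0, :], ov[:, -1, :]),     # y faces
                          (ov[0], ov[-1])]:                # z faces
            sq = np.concatenate([a.ravel() ** 2 for a in axis_vals])
            terms.append(sq.mean())
        assert got == pytest.approx(sum(terms), abs=1e-12)


class TestLossData:
    def _problem(self):
        grid = GridSpec(24, 24, 20e-9, 20e-9, 0.1327e-9)
        depth = DepthGrid(100e-6, 20e-9, 11)
        mask = disc_mask(grid, (12, 12), 6).astype(float)
        return grid, depth, mask

    def test_ground_truth_volume_is_self_consistent(self):
        from holofield.optics import ObjectVolume, multislice_forward, \
            multislice_forward_backward
        grid, depth, mask = self._problem()
        vol = ObjectVolume.empty(grid, depth.n_slices, phi=-0.3, A=0.03)
        vol.o_phi = vol.o_phi.copy(); vol.o_A = vol.o_A.copy()
        vol.o_phi[depth.center_index] = mask
        vol.o_A[depth.center_index] = mask
        H = multislice_forward(vol, depth, grid)
        _, loss, *_ = multislice_forward_backward(vol, depth, grid, hologram=H)
        assert loss < 1e-10

    def test_empty_volume_against_unit_hologram(self):
        from holofield.optics import ObjectVolume, multislice_forward_backward
        grid, depth, _ = self._problem()
        vol = ObjectVolume.empty(grid, depth.n_slices)
        _, loss, *_ = multislice_forward_backward(
            vol, depth, grid, hologram=np.ones(grid.shape))
        assert loss == pytest.approx(0.0, abs=1e-20)

    def test_loss_against_snl_hologram_is_near_shot_noise_floor(self):
        """With the exact object volume, the residual MSE against a noisy
        hologram equals the Poisson noise floor mean(lambda)/mu^2."""
        from holofield.optics import ObjectVolume, multislice_forward, \
            multislice_forward_backward
        from holofield.phantom import Hologram, apply_shot_noise
        grid, depth, mask = self._problem()
        vol = ObjectVolume.empty(grid, depth.n_slices, phi=-0.3, A=0.03)
        vol.o_phi = vol.o_phi.copy(); vol.o_A = vol.o_A.copy()
        vol.o_phi[depth.center_index] = mask
        vol.o_A[depth.center_index] = mask
        H = multislice_forward(vol, depth, grid)
        mu = 1000.0
        lam = mu * H / H.mean()
        floor = np.mean(lam) / mu ** 2
        losses = []
        for seed in range(10):
            noisy = apply_shot_noise(Hologram(H), mu, seed).intensity
            _, loss, *_ = multislice_forward_backward(vol, depth, grid,
                                                      hologram=noisy)
            losses.append(loss)
        assert np.mean(losses) == pytest.approx(floor, rel=0.2)


class TestGradients:
    def test_finite_difference_matches_reverse_mode(self):
        """End-to-end data-loss gradient on a 32x32, N=9 toy problem."""
        grid = GridSpec(32, 32, 10e-9, 10e-9, 0.1327e-9)
        depth = DepthGrid(100e-6, 20e-9, 9)
        phase, absorb, _ = render_phantom(three_disc_phantom(grid))
        H = simulate_hologram(phase, absorb, 100e-6, grid).intensity
        net = FieldNetwork(seed=3, dtype=np.float64)
        loss0, grads, d_phi, d_A = data_loss_and_param_grads(
            net, -0.3, 0.03, H, depth, grid)
        rng = np.random.default_rng(0)
        eps = 1e-6
        params = net.params
        for _ in range(5):
            li = int(rng.integers(len(params)))
            p = params[li]
            idx = tuple(int(rng.integers(s)) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, *_ = data_loss_and_param_grads(net, -0.3, 0.03, H, depth, grid)
            p[idx] = orig - eps
            lm, *_ = data_loss_and_param_grads(net, -0.3, 0.03, H, depth, grid)
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert fd == pytest.approx(grads[li][idx], rel=1e-4)

    def test_coefficient_gradients_match_finite_difference(self):
        grid = GridSpec(24, 24, 10e-9, 10e-9, 0.1327e-9)
        depth = DepthGrid(100e-6, 20e-9, 7)
        phase, absorb, _ = render_phantom(three_disc_phantom(grid))
        H = simulate_hologram(phase, absorb, 100e-6, grid).intensity
        net = FieldNetwork(seed=1, dtype=np.float64)
        _, _, d_phi, d_A = data_loss_and_param_grads(net, -0.3, 0.03, H,
                                                     depth, grid)
        eps = 1e-7
        lp, *_ = data_loss_and_param_grads(net, -0.3 + eps, 0.03, H, depth, grid)
        lm, *_ = data_loss_and_param_grads(net, -0.3 - eps, 0.03, H, depth, grid)
        assert (lp - lm) / (2 * eps) == pytest.approx(d_phi, rel=1e-4)
        lp, *_ = data_loss_and_param_grads(net, -0.3, 0.03 + eps, H, depth, grid)
        lm, *_ = data_loss_and_param_grads(net, -0.3, 0.03 - eps, H, depth, grid)
        assert (lp - lm) / (2 * eps) == pytest.approx(d_A, rel=1e-4)


class TestTrainingLoops:
    def test_pretraining_separates_object_from_background(self, tiny):
        grid, depth = tiny
        mask = disc_mask(grid, (8, 8), 4).astype(float)
        labels = build_label_stack(mask, depth, 5)
        net = FieldNetwork(seed=0)
        cfg = TrainConfig(pretrain_epochs=200, pretrain_lr=1e-3)
        hist = pretrain(net, labels, grid, cfg)
        assert hist[-1] < 0.02
        vol = materialize_volume(net, grid, depth, -0.3, 0.03)
        mid = vol.o_phi[depth.center_index]
        inside = mid[mask.astype(bool)].mean()
        outside = mid[~mask.astype(bool)].mean()
        assert inside - outside > 0.5

    def test_pretraining_loss_decreases_after_smoothing(self, tiny):
        grid, depth = tiny
        mask = disc_mask(grid, (8, 8), 4).astype(float)
        labels = build_label_stack(mask, depth, 5)
        net = FieldNetwork(seed=1)
        hist = np.array(pretrain(net, labels, grid,
                                 TrainConfig(pretrain_epochs=120)))
        smooth = np.convolve(hist, np.ones(10) / 10, mode="valid")
        # non-increasing trend allowing tiny numerical wiggle
        assert np.all(np.diff(smooth) < 1e-4)
        assert smooth[-1] < smooth[0]

    def test_zero_labels_drive_outputs_to_zero(self, tiny):
        grid, depth = tiny
        labels = MaskLabelStack(np.zeros((11, 16, 16)), 5, depth)
        net = FieldNetwork(seed=0)
        pretrain(net, labels, grid, TrainConfig(pretrain_epochs=300))
        o = net.forward(lattice_coords(grid, depth))
        assert o.mean() < 0.05

    def test_training_recovers_single_disc_phase(self):
        """Physics training on a noiseless single-disc hologram pulls the
        occupancy toward the true object: recovered in-disc phase within
        25% of truth after a short run, improving on pre-training alone."""
        grid = GridSpec(24, 24, 20e-9, 20e-9, 0.1327e-9)
        depth = DepthGrid(100e-6, 20e-9, 11)
        mask = disc_mask(grid, (12, 12), 5).astype(float)
        H = simulate_hologram(-0.3 * mask, 0.03 * mask, 100e-6, grid).intensity
        labels = build_label_stack(mask, depth, 5)
        net = FieldNetwork(seed=0, gaussian_scale=6.0)
        cfg = TrainConfig(pretrain_epochs=100, train_epochs=150,
                          train_lr=1e-3, early_stop_patience=None)
        pretrain(net, labels, grid, cfg)
        result = train(net, H, depth, grid, cfg, -0.3, 0.03, w_z=5)
        got = result.phase[mask.astype(bool)].mean()
        assert got == pytest.approx(-0.3, rel=0.25)
        assert result.history["data"][-1] < result.history["data"][0]

    def test_boundary_loss_suppresses_faces(self):
        grid = GridSpec(24, 24, 20e-9, 20e-9, 0.1327e-9)
        depth = DepthGrid(100e-6, 20e-9, 11)
        mask = disc_mask(grid, (12, 12), 5).astype(float)
        H = simulate_hologram(-0.3 * mask, 0.03 * mask, 100e-6, grid).intensity
        labels = build_label_stack(mask, depth, 5)
        net = FieldNetwork(seed=0, gaussian_scale=6.0)
        cfg = TrainConfig(pretrain_epochs=100, train_epochs=120,
                          train_lr=1e-3, early_stop_patience=None)
        pretrain(net, labels, grid, cfg)
        train(net, H, depth, grid, cfg, -0.3, 0.03, w_z=5)
        vol = materialize_volume(net, grid, depth, -0.3, 0.03)
        faces = np.concatenate([
            vol.o_phi[0].ravel(), vol.o_phi[-1].ravel(),
            vol.o_phi[:, 0, :].ravel(), vol.o_phi[:, -1, :].ravel(),
            vol.o_phi[:, :, 0].ravel(), vol.o_phi[:, :, -1].ravel()])
        assert faces.mean() < 0.05

    def test_extract_maps_single_slice_object(self, tiny):
        """A fully occupied single slice reproduces the coefficient."""
        grid, depth = tiny

        class FakeNet:
            def forward(self, coords):
                n = coords.shape[0]
                o = np.zeros((n, 2))
                vol_shape = (depth.n_slices, grid.ny, grid.nx)
                idx = np.arange(n).reshape(vol_shape)
                sel = np.zeros(vol_shape, bool)
                sel[depth.center_index] = True
                o[idx[sel]] = 1.0
                return o

        from holofield.field import extract_maps
        phase, absorb = extract_maps(FakeNet(), -0.3, 0.03, grid, depth,
                                     depth.window_indices(5))
        assert np.allclose(phase, -0.3)
        assert np.allclose(absorb, 0.03)

    def test_extract_maps_empty_volume(self, tiny):
        grid, depth = tiny

        class ZeroNet:
            def forward(self, coords):
                return np.zeros((coords.shape[0], 2))

        from holofield.field import extract_maps
        phase, absorb = extract_maps(ZeroNet(), -0.3, 0.03, grid, depth)
        assert np.allclose(phase, 0.0) and np.allclose(absorb, 0.0)

    def test_nan_hologram_raises_training_error(self, tiny):
        grid, depth = tiny
        from holofield.field import TrainingError
        net = FieldNetwork(seed=0)
        H = np.full(grid.shape, np.nan)
        cfg = TrainConfig(train_epochs=2)
        with pytest.raises(TrainingError):
            train(net, H, depth, grid, cfg, -0.3, 0.03)
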