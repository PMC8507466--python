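import numpy as np
import pytest

from spectsip.core import ValidationError
from spectsip.projector import AcquisitionGeometry, SystemModel, add_poisson_noise
from spectsip.sips import normalize, pack_input, sip_index_plan
from spectsip.unet import (
    NetworkConfig,
    TrainingConfig,
    build_network,
    load_checkpoint,
    masked_loss_and_grad,
    save_checkpoint,
    train_sip_network,
)


def tiny_config(side=8, depth=1, base=2, seed=0):
    return NetworkConfig(
        input_side=side, angle_slots=side, depth=depth, base_channels=base, seed=seed
    )


class TestArchitecture:
    def test_channel_doubling_and_halving(self):
        model = build_network(
            NetworkConfig(input_side=16, angle_slots=16, depth=3, base_channels=16)
        )
        assert model.encoder_channels == [16, 32, 64]
        assert model.bottleneck_channels == 128
        assert model.decoder_channels == [64, 32, 16]
        # weights realize the doubling/halving rules
        assert [c.W.shape[0] for c in model.enc_convs] == [16, 32, 64]
        assert [u.W.shape[1] for u in model.ups] == [64, 32, 16]
        assert model.head.W.shape[0] == 1

    def test_output_shape_equals_input_shape(self, rng):
        model = build_network(tiny_config(side=8, depth=2, base=2))
        x = rng.random((8, 8, 8))
        assert model.forward(x).shape == x.shape

    def test_seeded_initialization_is_deterministic(self):
        a = build_network(tiny_config(seed=5))
        b = build_network(tiny_config(seed=5))
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            np.testing.assert_array_equal(wa, wb)
        c = build_network(tiny_config(seed=6))
        assert any(
            not np.array_equal(wa, wc)
            for wa, wc in zip(a.get_weights(), c.get_weights())
        )

    def test_indivisible_dimensions_rejected(self):
        with pytest.raises(ValidationError):
            NetworkConfig(input_side=12, angle_slots=12, depth=3)


class TestGradients:
    def test_backprop_matches_numeric_gradient(self, rng):
        model = build_network(tiny_config(side=4, depth=1, base=2, seed=1))
        # shift biases off zero: ReLU pre-activations exactly at the kink make
        # numeric and analytic derivatives legitimately disagree
        for layer, name, _ in model.parameters():
            w = getattr(layer, name)
            w += 0.05 * rng.standard_normal(w.shape) + 0.01
        x = rng.random((4, 4, 4))
        tgt = rng.random((2, 4, 4))
        slot_idx = np.array([1, 3])

        def loss_value():
            return masked_loss_and_grad(model.forward(x), tgt, slot_idx, "L2")[0]

        base = model.forward(x)
        _, dout = masked_loss_and_grad(base, tgt, slot_idx, "L2")
        model.backward(dout)
        analytic = [getattr(l, gn).copy() for l, _, gn in model.parameters()]

        h = 1e-6
        checked = 0
        rng2 = np.random.default_rng(3)
        for (layer, name, _), grad in zip(model.parameters(), analytic):
            w = getattr(layer, name)
            flat = w.reshape(-1)
            for k in rng2.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + h
                up = loss_value()
                flat[k] = orig - h
                down = loss_value()
                flat[k] = orig
                numeric = (up - down) / (2 * h)
                assert numeric == pytest.approx(grad.reshape(-1)[k], rel=5e-3, abs=1e-8)
                checked += 1
        assert checked >= 20


class TestTraining:
    def _toy_dataset(self, rng, n=3, side=8):
        data = []
        for _ in range(n):
            x = rng.random((side, side, side))
            tgt = rng.random((2, side, side))
            data.append((x, tgt, np.array([1, 5])))
        return data

    def test_zero_learning_rate_keeps_parameters(self, rng):
        model = build_network(tiny_config())
        before = model.get_weights()
        tc = TrainingConfig(epochs=1, batch_size=2, learning_rate=0.0, seed=0)
        train_sip_network(model, self._toy_dataset(rng), tc)
        for wa, wb in zip(before, model.get_weights()):
            np.testing.assert_array_equal(wa, wb)

    def test_training_is_seed_reproducible(self, rng):
        data = self._toy_dataset(rng)
        tc = TrainingConfig(epochs=3, batch_size=2, learning_rate=1e-3, seed=11)
        _, h1 = train_sip_network(build_network(tiny_config(seed=2)), data, tc)
        _, h2 = train_sip_network(build_network(tiny_config(seed=2)), data, tc)
        assert h1 == h2

    def test_training_reduces_loss(self, rng):
        model = build_network(tiny_config(side=8, depth=1, base=4, seed=4))
        data = self._toy_dataset(rng, n=4)
        tc = TrainingConfig(epochs=10, batch_size=2, learning_rate=3e-3, seed=0)
        _, history = train_sip_network(model, data, tc)
        assert history[-1] < history[0]

    def test_empty_dataset_rejected(self):
        model = build_network(tiny_config())
        with pytest.raises(ValidationError):
            train_sip_network(model, [], TrainingConfig(epochs=1))


class TestEndToEndSIPQuality:
    def test_network_sips_beat_nearest_acquired_copy(self):
        """Sanity floor: a briefly trained net beats copying the nearest view."""
        from spectsip.phantoms import Ellipsoid, PhantomSpec, cohort_specs, generate_phantom
        from spectsip.projector import forward_project, subsample_sparse
        import dataclasses

        side, n_views = 16, 16
        geo = AcquisitionGeometry(n_angles=n_views, matrix_size=side, pixel_size_mm=4.42)
        model_sys = SystemModel(geometry=geo)
        base = PhantomSpec(
            grid_size=side, body=Ellipsoid((0, 0, 0), (30.0, 24.0, 28.0)),
            lesions=[],
        )
        plan = sip_index_plan(n_views)

        def make_pair(spec, noise_seed):
            act, att = generate_phantom(spec)
            full = forward_project(act, att, model_sys)
            full = dataclasses.replace(full, count_scale=2e4)
            noisy = add_poisson_noise(full, noise_seed)
            return noisy

        specs = cohort_specs(
            8, base, seed=21
        )
        train_data, held_out = [], None
        for i, spec in enumerate(specs):
            noisy = make_pair(spec, 100 + i)
            sparse = subsample_sparse(noisy)
            norm, scale = normalize(sparse)
            cube = pack_input(norm, angle_slots=n_views)
            idx = plan.sip_sets[0]
            target = noisy.counts[idx - 1] / scale
            sample = (cube, target, idx - 1)
            if i < 7:
                train_data.append(sample)
            else:
                held_out = (sample, noisy, sparse, scale)

        net = build_network(
            NetworkConfig(input_side=side, angle_slots=n_views, depth=2,
                          base_channels=4, seed=9)
        )
        tc = TrainingConfig(epochs=100, batch_size=4, learning_rate=3e-3, seed=13)
        _, history = train_sip_network(net, train_data, tc)
        assert history[-1] < history[0]

        (cube, target, slot_idx), noisy, sparse, scale = held_out
        pred = net.forward(cube)[:, :, slot_idx].transpose(2, 0, 1)
        net_rmse = float(np.sqrt(np.mean((pred - target) ** 2)))
        # nearest acquired view (set 1 -> preceding acquired view) as a floor
        nearest = sparse.counts / scale
        floor_rmse = float(np.sqrt(np.mean((nearest - target) ** 2)))
        assert net_rmse < floor_rmse


def test_checkpoint_round_trip(tmp_path, rng):
    model = build_network(tiny_config(seed=8))
    path = tmp_path / "net.npz"
    save_checkpoint(path, model, extra={"note": "fixture"})
    loaded, header = load_checkpoint(path)
    assert header["note"] == "fixture"
    x = rng.random((8, 8, 8))
    np.testing.assert_array_equal(model.forward(x), loaded.forward(x))
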