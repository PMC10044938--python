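"""Network contracts: shapes, symmetry, dense connectivity, gradients."""

import numpy as np
import pytest

from foldmap.encoding import N_CHANNELS, build_input_conformation
from foldmap.network import (BCM, DCM, NetworkConfig, PairScoreNet,
                             SequenceTooLongError, TransitionDown,
                             TransitionUp, load_checkpoint, residual_skip_add,
                             save_checkpoint)
from foldmap.nn import autograd as ag
from foldmap.nn.autograd import Tensor
from foldmap.nn.layers import BatchNorm2d, Conv2d

from conftest import random_sequence

TINY = NetworkConfig(feature_channels=8, dcm_layers_per_block=2, growth_rate=4,
                     num_levels=2, seed=0)


def rand_map(rng, n, c, h, w, requires_grad=False):
    return Tensor(rng.normal(0, 1, (n, c, h, w)), requires_grad=requires_grad)


class TestBCM:
    def test_shape_and_nonnegativity(self, rng):
        bcm = BCM(3, 5, 3, rng)
        out = bcm.forward(rand_map(rng, 2, 3, 8, 8))
        assert out.shape == (2, 5, 8, 8)
        assert (out.data >= 0).all()

    def test_channel_mismatch_raises(self, rng):
        bcm = BCM(3, 5, 3, rng)
        with pytest.raises(ValueError):
            bcm.forward(rand_map(rng, 2, 4, 8, 8))

    def test_zero_input_zero_parameters_zero_output(self, rng):
        bcm = BCM(3, 5, 3, rng)
        bcm.eval()
        for p in bcm.parameters():
            p.data[...] = 0.0
        out = bcm.forward(Tensor(np.zeros((1, 3, 6, 6))))
        assert not out.data.any()


class TestDCM:
    def test_depth_arithmetic(self, rng):
        x = rand_map(rng, 1, 16, 8, 8)
        enc = DCM(16, n_layers=4, growth=8, kernel_size=3, include_input=True,
                  rng=rng)
        assert enc.forward(x).shape[1] == 16 + 4 * 8 == enc.out_channels
        dec = DCM(16, n_layers=4, growth=8, kernel_size=3, include_input=False,
                  rng=rng)
        assert dec.forward(x).shape[1] == 4 * 8 == dec.out_channels

    def test_single_layer_degenerates_to_bcm(self, rng):
        x = rand_map(rng, 1, 6, 8, 8)
        dcm = DCM(6, n_layers=1, growth=4, kernel_size=3, include_input=False,
                  rng=rng)
        assert dcm.forward(x).shape[1] == 4

    def test_dense_connectivity_ablation(self, rng):
        # zeroing layer k's parameters must leave channels contributed
        # before k untouched (input block + outputs of layers < k)
        x = rand_map(rng, 1, 6, 8, 8)
        dcm = DCM(6, n_layers=3, growth=4, kernel_size=3, include_input=True,
                  rng=rng)
        dcm.eval()
        before = dcm.forward(x).data.copy()
        k = 1
        for p in dcm.layers[k].parameters():
            p.data[...] = 0.0
        after = dcm.forward(x).data
        untouched = 6 + k * 4  # input channels + outputs of layers < k
        assert np.array_equal(before[:, :untouched], after[:, :untouched])
        assert not np.array_equal(before[:, untouched:], after[:, untouched:])


class TestTransitions:
    def test_down_halves_up_doubles(self, rng):
        x = rand_map(rng, 1, 6, 16, 16)
        td = TransitionDown(6, 3, rng)
        down = td.forward(x)
        assert down.shape == (1, 6, 8, 8)
        tu = TransitionUp(6, 4, 3, rng)
        up = tu.forward(down)
        assert up.shape == (1, 4, 16, 16)  # spatial size restored, depth down

    def test_repeated_down(self, rng):
        x = rand_map(rng, 1, 2, 64, 64)
        td = TransitionDown(2, 3, rng)
        for _ in range(4):
            x = td.forward(x)
        assert x.shape[-2:] == (4, 4)

    def test_odd_size_rejected(self, rng):
        with pytest.raises(ValueError):
            ag.maxpool2(rand_map(rng, 1, 2, 7, 7))


class TestSkipAdd:
    def test_zero_encoder_map_is_identity(self, rng):
        d = rand_map(rng, 1, 3, 4, 4)
        z = Tensor(np.zeros((1, 3, 4, 4)))
        assert np.array_equal(residual_skip_add(d, z).data, d.data)

    def test_commutative(self, rng):
        a, b = rand_map(rng, 1, 3, 4, 4), rand_map(rng, 1, 3, 4, 4)
        assert np.array_equal(residual_skip_add(a, b).data,
                              residual_skip_add(b, a).data)

    def test_shape_mismatch_is_wiring_error(self, rng):
        with pytest.raises(ValueError):
            residual_skip_add(rand_map(rng, 1, 3, 4, 4),
                              rand_map(rng, 1, 3, 8, 8))


class TestSymmetrization:
    def test_antisymmetric_raw_cancels(self, rng):
        r = rng.normal(0, 1, (1, 1, 6, 6))
        anti = r - r.transpose(0, 1, 3, 2)
        t = Tensor(anti)
        out = ag.add(t, ag.transpose_spatial(t))
        assert np.abs(out.data).max() == 0.0

    @pytest.mark.parametrize("L", [17, 33, 64])
    def test_output_symmetric_with_random_weights(self, rng, L):
        model = PairScoreNet(TINY)
        S = model.predict(random_sequence(rng, L))
        assert S.shape == (L, L)
        assert np.abs(S - S.T).max() <= 1e-5


class TestForward:
    def test_non_multiple_length_padded_and_cropped(self, rng):
        model = PairScoreNet(TINY)
        S = model.predict(random_sequence(rng, 13))
        assert S.shape == (13, 13)

    def test_feature_extraction_depth_matches_config(self, rng):
        model = PairScoreNet(TINY)
        model.predict(random_sequence(rng, 12))
        assert model.feature_depth_ == TINY.feature_channels

    def test_overlength_refused(self, rng):
        model = PairScoreNet(NetworkConfig(feature_channels=4,
                                           dcm_layers_per_block=1,
                                           growth_rate=4, num_levels=1,
                                           max_length=50))
        with pytest.raises(SequenceTooLongError):
            model.predict(random_sequence(rng, 51))

    def test_seeded_determinism(self, rng):
        seq = random_sequence(rng, 20)
        a = PairScoreNet(TINY).predict(seq)
        b = PairScoreNet(TINY).predict(seq)
        assert np.array_equal(a, b)

    def test_gradient_reaches_first_convolution(self, rng):
        model = PairScoreNet(TINY)
        L, H = 12, 16
        x = np.zeros((1, N_CHANNELS, H, H), dtype=np.float32)
        x[0, :, :L, :L] = build_input_conformation(random_sequence(rng, L)).tensor
        scores = model.forward_batch(x, [L])
        target = np.zeros((1, 1, H, H), dtype=np.float32)
        target[0, 0, 2, 8] = target[0, 0, 8, 2] = 1
        mask = np.zeros_like(target)
        mask[0, 0, :L, :L] = np.triu(np.ones((L, L)), k=4)
        loss = ag.weighted_bce_with_logits(scores, target, mask, 5.0)
        loss.backward()
        first_conv_w = model.feature_extraction[0].conv._params["weight"]
        assert first_conv_w.grad is not None
        assert np.abs(first_conv_w.grad).max() > 0


class TestGradients:
    def test_numeric_gradient_of_composite(self, rng):
        """Finite-difference check through conv/bn/pool/upsample/loss."""
        x = Tensor(rng.normal(0, 1, (2, 3, 8, 8)), requires_grad=True)
        conv = Conv2d(3, 4, 3, rng)
        bn = BatchNorm2d(4)
        head = Conv2d(4, 1, 1, rng)
        target = (rng.random((2, 1, 8, 8)) < 0.2).astype(np.float32)
        mask = np.ones((2, 1, 8, 8), np.float32)

        def forward():
            t = ag.relu(bn.forward(conv.forward(x)))
            t = ag.upsample_nearest2(ag.maxpool2(t))
            r = head.forward(t)
            s = ag.add(r, ag.transpose_spatial(r))
            return ag.weighted_bce_with_logits(s, target, mask, 3.0)

        forward().backward()
        w = conv._params["weight"]
        got = w.grad.copy()
        eps = 1e-2
        for idx in [(0, 0, 0, 0), (3, 2, 1, 1), (1, 1, 2, 0)]:
            old = w.data[idx]
            w.data[idx] = old + eps
            fp = float(forward().data)
            w.data[idx] = old - eps
            fm = float(forward().data)
            w.data[idx] = old
            num = (fp - fm) / (2 * eps)
            assert got[idx] == pytest.approx(num, rel=0.05, abs=1e-4)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, rng, tmp_path):
        model = PairScoreNet(TINY)
        seq = random_sequence(rng, 18)
        before = model.predict(seq)
        p = tmp_path / "model.npz"
        save_checkpoint(model, p)
        restored = load_checkpoint(p)
        assert restored.cfg == model.cfg
        assert np.array_equal(restored.predict(seq), before)

    def test_config_yaml_round_trip(self, tmp_path):
        p = tmp_path / "net.yaml"
        TINY.to_yaml(p)
        assert NetworkConfig.from_yaml(p) == TINY

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(kernel_size=4)
        with pytest.raises(ValueError):
            NetworkConfig(num_levels=0)
        assert NetworkConfig(num_levels=3).pad_multiple == 8
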