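"""Architecture contracts: shapes, scope flexibility, permutation
equivariance, and path locality of the pair/scope classifier."""

import numpy as np
import pytest

from ecgscope.model import (
    COMPOSITE_LENGTH, N_TOKENS_PER_SEGMENT, ECGPairClassifier, ModelConfig,
    load_checkpoint, save_checkpoint,
)
from ecgscope.autograd import Tensor, no_grad


@pytest.fixture(scope="module")
def tiny_model():
    m = ECGPairClassifier(ModelConfig.scaled(1 / 16, seed=0))
    m.eval()
    return m


@pytest.fixture(scope="module")
def segments():
    rng = np.random.default_rng(0)

    def make(n):
        x = rng.normal(size=(n, 384))
        return ((x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
                ).astype(np.float32)

    return make


class TestGeometry:
    def test_token_counts(self):
        assert N_TOKENS_PER_SEGMENT == 22
        assert COMPOSITE_LENGTH == 46

    def test_expansion_default_config_is_22x512(self):
        m = ECGPairClassifier(ModelConfig())
        m.eval()
        rng = np.random.default_rng(1)
        seg = rng.normal(size=(1, 384)).astype(np.float32)
        with no_grad():
            out = m.feature_space_expansion(Tensor(seg))
        assert out.shape == (1, 22, 512)
        assert (out.data >= 0).all()          # max of ReLU outputs

    def test_prepool_length_is_352(self, tiny_model, segments):
        x = Tensor(segments(1))
        with no_grad():
            y = tiny_model.conv(x)
        assert y.shape[1] == 384 - 33 + 1 == 352

    def test_composite_layout(self, tiny_model, segments):
        d = tiny_model.config.d_model
        with no_grad():
            xk = tiny_model.feature_space_expansion(Tensor(segments(3)))
            xq = tiny_model.feature_space_expansion(Tensor(segments(3)))
            seq = tiny_model.build_composite_sequence(xk, xq)
        assert seq.shape == (3, 46, d)
        # without embeddings/positions, tokens 2-23 would equal Xk; with
        # them, the difference is exactly Ee + position embedding
        delta = seq.data[:, 2:24, :] - xk.data
        expected = (tiny_model.emb_enrolled.data
                    + tiny_model.pos_emb.data[2:24])
        assert np.allclose(delta, expected[None], atol=1e-6)

    def test_wrong_segment_length_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.feature_space_expansion(Tensor(np.zeros((1, 100))))

    def test_scaled_config_keeps_token_geometry(self):
        cfg = ModelConfig.scaled(1 / 8)
        assert cfg.d_model == 64 and cfg.feedforward_dim == 256
        assert cfg.verification_head_widths == (64, 64, 64, 64, 32, 16)


class TestForward:
    def test_output_shapes_and_normalization(self, tiny_model, segments):
        out = tiny_model.predict(segments(8).reshape(2, 4, 384), segments(2))
        assert out.verification_probs.shape == (2, 4)
        assert out.id_distribution.shape == (2, 4)
        assert ((0 < out.verification_probs) & (out.verification_probs < 1)).all()
        assert np.allclose(out.id_distribution.sum(axis=1), 1.0, atol=1e-5)

    def test_eval_mode_deterministic(self, tiny_model, segments):
        scope, query = segments(4).reshape(1, 4, 384), segments(1)
        a = tiny_model.predict(scope, query)
        b = tiny_model.predict(scope, query)
        assert np.array_equal(a.verification_probs, b.verification_probs)
        assert np.array_equal(a.id_distribution, b.id_distribution)

    @pytest.mark.parametrize("h", [1, 2, 5, 64])
    def test_scope_flexibility(self, tiny_model, segments, h):
        # one parameter set serves any h with valid, normalized outputs
        out = tiny_model.predict(segments(h).reshape(1, h, 384), segments(1))
        assert out.verification_probs.shape == (1, h)
        assert np.isclose(out.id_distribution.sum(), 1.0, atol=1e-5)
        if h == 1:
            assert np.isclose(out.id_distribution[0, 0], 1.0)

    def test_permutation_equivariance(self, tiny_model, segments):
        scope = segments(6).reshape(1, 6, 384)
        query = segments(1)
        base = tiny_model.predict(scope, query)
        rng = np.random.default_rng(3)
        perm = rng.permutation(6)
        permuted = tiny_model.predict(scope[:, perm], query)
        assert np.allclose(permuted.id_distribution[0],
                           base.id_distribution[0][perm], atol=1e-5)
        assert np.allclose(permuted.verification_probs[0],
                           base.verification_probs[0][perm], atol=1e-5)

    def test_duplicate_scope_segment_equal_probs(self, tiny_model, segments):
        scope = segments(4)
        scope[2] = scope[0]
        out = tiny_model.predict(scope.reshape(1, 4, 384), segments(1))
        assert np.allclose(out.verification_probs[0, 0],
                           out.verification_probs[0, 2], atol=1e-5)

    def test_verification_locality_identification_globality(
            self, tiny_model, segments):
        # editing G_j (j != k) must not change verification prob k, but
        # generally changes the identification distribution
        scope = segments(5).reshape(1, 5, 384)
        query = segments(1)
        base = tiny_model.predict(scope, query)
        edited = scope.copy()
        edited[0, 3] = segments(1)[0]
        out = tiny_model.predict(edited, query)
        keep = [0, 1, 2, 4]
        assert np.allclose(out.verification_probs[0, keep],
                           base.verification_probs[0, keep], atol=1e-6)
        assert not np.allclose(out.id_distribution, base.id_distribution,
                               atol=1e-6)

    def test_pair_encoder_sensitive_to_enrolled_content(self, tiny_model, segments):
        with no_grad():
            xk = tiny_model.feature_space_expansion(Tensor(segments(1)))
            xq = tiny_model.feature_space_expansion(Tensor(segments(1)))
            l_ve1, _ = tiny_model.ecg_pair_encode(
                tiny_model.build_composite_sequence(xk, xq))
            xk2 = tiny_model.feature_space_expansion(Tensor(segments(1)))
            l_ve2, _ = tiny_model.ecg_pair_encode(
                tiny_model.build_composite_sequence(xk2, xq))
        assert np.abs(l_ve1.data - l_ve2.data).max() > 1e-4

    def test_empty_scope_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.id_encode(Tensor(np.zeros((1, 0, 32), np.float32)))


class TestHeads:
    def test_verification_head_parameter_count(self):
        # closed form over the stated widths:
        # [FC512+BN+ReLU]x4, FC256+BN, FC128+BN, FC1+BN(+sigmoid)
        m = ECGPairClassifier(ModelConfig())
        widths = [512, 512, 512, 512, 512, 256, 128, 1]
        expected = sum(i * o + o for i, o in zip(widths[:-1], widths[1:]))
        expected += sum(2 * o for o in widths[1:])     # BN gamma+beta each
        got = sum(p.data.size
                  for name, p in m.named_parameters().items()
                  if name.startswith("verify_layers"))
        assert got == expected

    def test_id_classifier_uniform_on_identical_inputs(self, tiny_model):
        d = tiny_model.config.d_model
        vec = np.random.default_rng(5).normal(size=d).astype(np.float32)
        hidden = np.tile(vec, (1, 7, 1))
        with no_grad():
            dist = tiny_model.id_classify(Tensor(hidden))
        assert np.allclose(dist.data, 1 / 7, atol=1e-6)

    def test_id_encoder_permutation_equivariant(self, tiny_model):
        rng = np.random.default_rng(6)
        feats = rng.normal(size=(1, 9, tiny_model.config.d_model)
                           ).astype(np.float32)
        perm = rng.permutation(9)
        with no_grad():
            a = tiny_model.id_encode(Tensor(feats)).data
            b = tiny_model.id_encode(Tensor(feats[:, perm])).data
        assert np.allclose(b, a[:, perm], atol=1e-5)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tiny_model, segments, tmp_path):
        scope, query = segments(4).reshape(1, 4, 384), segments(1)
        before = tiny_model.predict(scope, query)
        path = save_checkpoint(tiny_model, tmp_path / "m.npz",
                               extra={"note": "test"})
        back, extra = load_checkpoint(path)
        assert extra["note"] == "test"
        after = back.predict(scope, query)
        assert np.allclose(before.verification_probs,
                           after.verification_probs, atol=1e-7)
        assert np.allclose(before.id_distribution,
                           after.id_distribution, atol=1e-7)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(d_model=100)           # not divisible by 8 heads
        with pytest.raises(ValueError):
            ModelConfig(conv_filters=256)      # must match d_model
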