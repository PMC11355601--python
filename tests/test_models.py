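"""Architectures: shapes, determinism, softmax normalisation, λ-invariant
forward, checkpoints."""

import numpy as np
import pytest

from dermadapt.models import (FeatureExtractorSpec, assemble_baseline,
                              assemble_dann, build_feature_extractor, forward,
                              load_checkpoint, save_checkpoint,
                              summarize_parameters)
from dermadapt.nn import ForwardContext, Tensor

RNG = np.random.default_rng(77)


def images(n, s):
    return RNG.random((n, 3, s, s)).astype(np.float32)


class TestFeatureExtractorSpec:
    def test_unknown_kind_lists_valid(self):
        with pytest.raises(ValueError, match="cnn_dropout"):
            FeatureExtractorSpec("resnet")

    def test_input_size_power_of_two(self):
        with pytest.raises(ValueError):
            FeatureExtractorSpec("cnn_dropout", 48)
        with pytest.raises(ValueError):
            FeatureExtractorSpec("vgg13", 16)

    def test_alexnet_needs_64(self):
        with pytest.raises(ValueError, match="64"):
            FeatureExtractorSpec("alexnet", 32)


@pytest.mark.parametrize("kind,size", [("cnn_dropout", 64), ("alexnet", 64),
                                       ("vgg11", 64), ("vgg13", 64),
                                       ("cnn_dropout", 32)])
def test_extractor_output_shape_matches_declared_dim(kind, size):
    spec = FeatureExtractorSpec(kind, size)
    fe = build_feature_extractor(spec, seed=1)
    out = fe(Tensor(images(2, size)), ForwardContext(train=False))
    assert out.shape == (2, spec.feature_dim)


def test_vgg13_feature_dim_traced_by_hand():
    # ten 3x3 same-pad convs, five 2x2 pools: 64 -> 2; 512 channels out
    assert FeatureExtractorSpec("vgg13", 64).feature_dim == 512 * 2 * 2


def test_same_seed_same_parameters_different_seed_differs():
    spec = FeatureExtractorSpec("cnn_dropout", 32)
    a = build_feature_extractor(spec, seed=3)
    b = build_feature_extractor(spec, seed=3)
    c = build_feature_extractor(spec, seed=4)
    for (na, pa), (_, pb), (_, pc) in zip(a.named_parameters(),
                                          b.named_parameters(),
                                          c.named_parameters()):
        assert np.array_equal(pa.data, pb.data), na
        if "conv" in na and "weight" in na:
            assert not np.array_equal(pa.data, pc.data)


class TestDANNAssembly:
    def test_variant_invariants(self):
        d = assemble_dann(FeatureExtractorSpec("cnn_dropout", 32), "dann", 0)
        assert d.grl_secondary is None
        t = assemble_dann(FeatureExtractorSpec("cnn_dropout", 32),
                          "two_grl_dann", 0)
        assert t.grl_secondary is not None
        with pytest.raises(ValueError, match="variant"):
            assemble_dann(FeatureExtractorSpec("cnn_dropout", 32), "dcnn", 0)

    @pytest.mark.parametrize("variant", ["dann", "two_grl_dann"])
    def test_forward_row_stochastic(self, variant):
        model = assemble_dann(FeatureExtractorSpec("cnn_dropout", 32),
                              variant, seed=2)
        cp, dp = forward(model, images(4, 32))
        for probs in (cp, dp):
            assert probs.shape == (4, 2)
            assert (probs >= 0).all() and (probs <= 1).all()
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_single_image_batch(self):
        model = assemble_dann(FeatureExtractorSpec("cnn_dropout", 32),
                              "dann", seed=2)
        cp, dp = forward(model, images(1, 32))
        assert cp.shape == (1, 2) and dp.shape == (1, 2)

    def test_forward_independent_of_lambda(self):
        model = assemble_dann(FeatureExtractorSpec("cnn_dropout", 32),
                              "dann", seed=2)
        batch = images(3, 32)
        model.grl_primary.value = 0.0
        a = forward(model, batch)
        model.grl_primary.value = 1.0
        b = forward(model, batch)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_two_models_same_seed_identical_outputs(self):
        spec = FeatureExtractorSpec("cnn_dropout", 32)
        batch = images(3, 32)
        a = forward(assemble_dann(spec, "dann", seed=5), batch)
        b = forward(assemble_dann(spec, "dann", seed=5), batch)
        assert np.array_equal(a[0], b[0])

    def test_wrong_spatial_size_names_expected(self):
        model = assemble_dann(FeatureExtractorSpec("cnn_dropout", 64),
                              "dann", seed=0)
        with pytest.raises(ValueError, match="64"):
            forward(model, images(2, 32))


def test_two_grl_severed_at_lambda_zero():
    """With both λ = 0, the gradient into the feature extractor equals the
    gradient from the class loss alone."""
    from dermadapt.nn import functional as F
    from dermadapt.training import dann_step_loss

    spec = FeatureExtractorSpec("cnn_dropout", 32)
    batch = images(8, 32)
    labels = np.array([0, 1] * 4)
    d_lab = np.r_[np.zeros(4, np.int64), np.ones(4, np.int64)]

    def fe_grads(with_domain):
        model = assemble_dann(spec, "two_grl_dann", seed=9)
        model.grl_primary.value = 0.0
        model.grl_secondary.value = 0.0
        ctx = ForwardContext(True, 9, 0, tag=0)
        feats = model.fe(Tensor(batch), ctx)
        h1, cp = model.class_branch(feats, ctx)
        loss = F.cross_entropy_from_probs(cp, labels)
        if with_domain:
            tap = model.label_predictor.block1(feats, ForwardContext(
                True, 9, 0, tag=1, bn_stats="batch_nobuf"))
            dp = model.domain_branch(feats, ctx, cl_tap=tap)
            loss, _, _ = dann_step_loss(cp, labels, dp, d_lab, 0.0)
        for p in model.parameters():
            p.grad = None
        loss.backward()
        return {n: p.grad for n, p in model.fe.named_parameters()}

    g_class = fe_grads(with_domain=False)
    g_full = fe_grads(with_domain=True)
    for name in g_class:
        np.testing.assert_array_equal(g_class[name], g_full[name])


def test_parameter_summary_stable_across_runs():
    spec = FeatureExtractorSpec("cnn_dropout", 64)
    a = summarize_parameters(assemble_dann(spec, "dann", seed=1))
    b = summarize_parameters(assemble_dann(spec, "dann", seed=1))
    assert a == b
    total = sum(cnt for _, _, cnt in a)
    assert total > 1_000_000  # FC head on 4096-d features dominates


def test_checkpoint_round_trip(tmp_path):
    model = assemble_dann(FeatureExtractorSpec("cnn_dropout", 32),
                          "two_grl_dann", seed=6)
    model.grl_primary.value = 0.7
    batch = images(2, 32)
    before = forward(model, batch)
    path = save_checkpoint(model, tmp_path / "ckpt")
    restored = load_checkpoint(path)
    after = forward(restored, batch)
    assert np.array_equal(before[0], after[0])
    assert restored.grl_primary.value == pytest.approx(0.7)
    assert restored.variant == "two_grl_dann"


def test_baseline_shares_initialisation_with_dann():
    spec = FeatureExtractorSpec("cnn_dropout", 32)
    d = assemble_dann(spec, "dann", seed=12)
    b = assemble_baseline(spec, seed=12)
    for (nd, pd), (nb, pb) in zip(
            list(d.fe.named_parameters()) +
            list(d.label_predictor.named_parameters()),
            b.named_parameters()):
        assert nd == nb
        assert np.array_equal(pd.data, pb.data)
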