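"""Training protocol, affine augmentation, and tile-and-stitch inference."""

import numpy as np
import pytest

from specseg.model import (
    AugmentRanges,
    ModalityConfig,
    TrainConfig,
    TrainedModel,
    apply_affine,
    augment_affine,
    build_model,
    predict_section,
    train,
)
from specseg.patches import Patch, build_manifest
from specseg.preprocess import ChannelStats, LabelMap, MultimodalStack, ParameterError


def _make_patch(size=32, n_channels=3, seed=0, labels=None):
    r = np.random.default_rng(seed)
    if labels is None:
        labels = r.integers(1, 4, (size, size)).astype(np.uint8)
    return Patch(
        channels=r.random((n_channels, size, size)).astype(np.float32),
        labels=labels,
        mask=np.ones((size, size), bool),
        section_id="s0",
        origin=(0, 0),
        tissue_frac=1.0,
    )


def _tiny_manifest(n_train=2, size=32):
    patches = {
        "s0": [_make_patch(size, seed=i) for i in range(n_train)],
        "s1": [_make_patch(size, seed=50)],
        "s2": [_make_patch(size, seed=60)],
    }
    stats = ChannelStats(mean=np.zeros(3), sd=np.ones(3))
    return build_manifest(
        {"train": ["s0"], "val": ["s1"], "test": ["s2"]}, patches, stats=stats
    )


_FAST = dict(backbone="reduced", batch_size=2, n_replicates=1,
             augment=AugmentRanges(0, 0, 1.0, 1.0, 0))


class TestModalityAndBuild:
    def test_channel_selectors(self):
        assert ModalityConfig("DF").channel_selector == (2,)
        assert ModalityConfig("IR").channel_selector == (0, 1)
        assert ModalityConfig("COMBINED").channel_selector == (0, 1, 2)
        with pytest.raises(ParameterError):
            ModalityConfig("RGB")

    def test_first_layer_matches_modality(self):
        net = build_model(ModalityConfig("DF"), backbone="reduced")
        assert net.in_channels == 1
        net = build_model(ModalityConfig("COMBINED"), backbone="reduced")
        assert net.in_channels == 3


class TestAugmentAffine:
    def test_identity_draw_bit_equal(self, rng):
        p = _make_patch()
        out = augment_affine(p, rng, AugmentRanges(0, 0, 1.0, 1.0, 0))
        assert np.array_equal(out.channels, p.channels)
        assert np.array_equal(out.labels, p.labels)
        assert np.array_equal(out.mask, p.mask)

    def test_right_angle_rotation_is_exact_permutation(self):
        labels = np.zeros((32, 32), np.uint8)
        labels[:16, :16] = 2  # class 2 in the top-left quadrant
        labels[labels == 0] = 1
        p = _make_patch(labels=labels)
        out = apply_affine(p, rotation_deg=90.0)
        assert (out.labels == 2).sum() == (labels == 2).sum()
        # oracle: exact index permutation for a quarter turn
        assert np.array_equal(out.labels, np.rot90(labels, k=1)) or np.array_equal(
            out.labels, np.rot90(labels, k=-1)
        )
        # the quadrant moved off the top-left
        assert not (out.labels[:16, :16] == 2).all()

    def test_label_values_stay_legal_over_random_draws(self, rng):
        p = _make_patch()
        for _ in range(10):
            out = augment_affine(p, rng, AugmentRanges())
            assert set(np.unique(out.labels)) <= {0, 1, 2, 3}
            assert out.channels.shape == p.channels.shape

    def test_out_of_frame_filled_with_background(self, rng):
        p = _make_patch()
        out = apply_affine(p, translate=(10.0, 0.0))
        assert (out.labels[:8] == 0).all()
        assert np.allclose(out.channels[:, :8], 0.0)


class TestTrain:
    def test_zero_epochs_returns_initialized_models(self):
        man = _tiny_manifest()
        cfg = TrainConfig(max_epochs=0, **_FAST)
        models = train(man, ModalityConfig("COMBINED"), cfg)
        assert len(models) == 1
        assert models[0].history == []

    def test_lr_trace_follows_step_schedule_for_15_epochs(self):
        man = _tiny_manifest(n_train=1)
        cfg = TrainConfig(max_epochs=15, early_stopping_patience=100, **_FAST)
        (model,) = train(man, ModalityConfig("IR"), cfg)
        lrs = [h["lr"] for h in model.history]
        assert lrs == [2e-4 * 0.5 ** (e // 5) for e in range(15)]

    def test_replicate_determinism_and_distinct_seeds(self):
        man = _tiny_manifest()
        cfg = TrainConfig(max_epochs=2, early_stopping_patience=100,
                          backbone="reduced", batch_size=2, n_replicates=2,
                          augment=AugmentRanges(0, 0, 1.0, 1.0, 0), seed=3)
        a = train(man, ModalityConfig("COMBINED"), cfg)
        b = train(man, ModalityConfig("COMBINED"), cfg)
        assert a[0].history == b[0].history
        assert a[1].history == b[1].history
        assert a[0].history != a[1].history  # different derived seeds

    def test_empty_split_errors(self):
        patches = {"s0": [_make_patch()], "s1": [], "s2": []}
        man = build_manifest(
            {"train": ["s0"], "val": ["s1"], "test": ["s2"]},
            patches,
            stats=ChannelStats(mean=np.zeros(3), sd=np.ones(3)),
        )
        with pytest.raises(ParameterError):
            train(man, ModalityConfig("IR"), TrainConfig(max_epochs=1, **_FAST))


class _ConstNet:
    """Stub network producing the same class scores everywhere."""

    def __init__(self, scores=(0.2, 1.7, -0.5)):
        self.scores = np.asarray(scores, np.float32)
        self.n_classes = 3
        self.stride_product = 1
        self.in_channels = 3

    def forward(self, x):
        b, _, h, w = x.shape
        return np.broadcast_to(self.scores[None, :, None, None], (b, 3, h, w)).copy()

    def train(self, mode=True):
        pass


def _stub_model(modality="COMBINED"):
    return TrainedModel(
        network=_ConstNet(),
        modality=ModalityConfig(modality),
        train_config=TrainConfig(backbone="reduced"),
        stats=ChannelStats(mean=np.zeros(3), sd=np.ones(3)),
        history=[],
        replicate=0,
    )


def _section_stack(h=256, w=256, seed=0, mask=None):
    r = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones((h, w), bool)
    return MultimodalStack(
        channels=r.random((3, h, w)).astype(np.float32),
        tissue_mask=mask,
        section_id="sec",
        stats=ChannelStats(mean=np.zeros(3), sd=np.ones(3)),
    )


class TestPredictSection:
    def test_single_tile_equivalence(self):
        stack = _section_stack(128, 128)
        model = _stub_model()
        pred = predict_section(model, stack, tile=128, overlap=0)
        # constant stub puts every masked pixel in the argmax class (2)
        assert (pred.labels == 2).all()

    def test_stitching_invariant_for_constant_stub(self):
        stack = _section_stack(256, 256)
        model = _stub_model()
        ref = predict_section(model, stack, tile=128, overlap=0).labels
        for tile in (128, 256):
            for overlap in (0, 32):
                got = predict_section(model, stack, tile=tile, overlap=overlap).labels
                assert np.array_equal(got, ref)

    def test_mask_supremacy(self):
        stack = _section_stack(128, 128, mask=np.zeros((128, 128), bool))
        pred = predict_section(_stub_model(), stack, tile=128, overlap=0)
        assert (pred.labels == 0).all()

    def test_bad_tile_parameters_rejected(self):
        stack = _section_stack(128, 128)
        model = _stub_model()
        model.network.stride_product = 8
        with pytest.raises(ParameterError):
            predict_section(model, stack, tile=4, overlap=0)
        with pytest.raises(ParameterError):
            predict_section(model, stack, tile=128, overlap=128)
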