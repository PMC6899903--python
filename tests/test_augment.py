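"""The three augmentation procedures and their exact identities."""

import numpy as np
import pytest

from contactnet.augment import (
    AugmentConfig,
    TrainingExample,
    augment_batch,
    flip_example,
    interpolate_features,
    loop_sampling,
)
from contactnet.features import FeatureTensor, separation_channel, stripe_1d
from contactnet.pipeline import family_to_example
from contactnet.synthetic import make_family, residue_features


@pytest.fixture(scope="module")
def example():
    rng = np.random.default_rng(31)
    fam = make_family(40, 30, 10, rng, 1.0)
    return family_to_example(fam)


def clone(ex: TrainingExample) -> TrainingExample:
    return TrainingExample(
        x=FeatureTensor(ex.x.data.copy(), list(ex.x.channel_map), dict(ex.x.metadata)),
        y=ex.y.copy(),
        loop_mask=ex.loop_mask.copy(),
        x_alt=None
        if ex.x_alt is None
        else FeatureTensor(ex.x_alt.data.copy(), list(ex.x_alt.channel_map), dict(ex.x_alt.metadata)),
    )


class TestLoopSampling:
    def test_loop_rich_protein_unchanged(self, example):
        ex = clone(example)
        ex.loop_mask = np.ones(ex.L, dtype=bool)  # 100% loop
        out = loop_sampling(ex, AugmentConfig(p_loop_apply=1.0, p_residue_del=1.0, max_loop_frac=0.4), np.random.default_rng(0))
        assert out is ex

    def test_apply_coin_failure_is_identity(self, example):
        out = loop_sampling(example, AugmentConfig(p_loop_apply=0.0), np.random.default_rng(0))
        assert out is example

    def test_no_deletions_is_identity(self, example):
        out = loop_sampling(
            example, AugmentConfig(p_loop_apply=1.0, p_residue_del=0.0), np.random.default_rng(0)
        )
        assert out is example

    def test_deletion_shrinks_and_recomputes_separation(self, example):
        cfg = AugmentConfig(p_loop_apply=1.0, p_residue_del=0.5)
        out = loop_sampling(example, cfg, np.random.default_rng(5))
        n_del = example.L - out.L
        assert n_del > 0
        np.testing.assert_array_equal(out.x.channel("separation"), separation_channel(out.L))
        np.testing.assert_array_equal(out.x.channel("bounds"), 1)

    def test_never_deletes_non_loop_residues(self, example):
        cfg = AugmentConfig(p_loop_apply=1.0, p_residue_del=1.0)
        out = loop_sampling(example, cfg, np.random.default_rng(1))
        # all loop residues deleted -> survivors are exactly the non-loop set
        assert out.L == int((~example.loop_mask).sum())
        assert not out.loop_mask.any()
        keep = ~example.loop_mask
        np.testing.assert_array_equal(out.y, example.y[keep][:, keep])

    def test_striped_channels_rebuild_equivalence(self, example):
        """Excising rows/columns of a stripe equals striping the excised vector."""
        cfg = AugmentConfig(p_loop_apply=1.0, p_residue_del=0.5)
        out = loop_sampling(example, cfg, np.random.default_rng(5))
        keep = np.ones(example.L, dtype=bool)
        # reconstruct the kept index set from the surviving length
        deleted = example.L - out.L
        rng = np.random.default_rng(5)
        rng.random()  # the apply coin
        delete = example.loop_mask & (rng.random(example.L) < cfg.p_residue_del)
        keep = ~delete
        assert int(delete.sum()) == deleted
        solv = example.x.channel("solv_h")[:, 0]
        rebuilt = stripe_1d(solv[keep])
        np.testing.assert_array_equal(out.x.channel("solv_h"), rebuilt[0])
        np.testing.assert_array_equal(out.x.channel("solv_v"), rebuilt[1])


class TestInterpolation:
    def test_endpoints_exact(self, example):
        x1, x2 = example.x, example.x_alt
        np.testing.assert_array_equal(interpolate_features(x1, x2, 1.0).data, x1.data)
        np.testing.assert_array_equal(interpolate_features(x1, x2, 0.0).data, x2.data)

    def test_midpoint_of_constants(self):
        names = ["a", "b"]
        x0 = FeatureTensor(np.zeros((2, 3, 3)), names)
        x2 = FeatureTensor(np.full((2, 3, 3), 2.0), names)
        np.testing.assert_array_equal(interpolate_features(x0, x2, 0.5).data, 1.0)

    def test_linearity(self, example):
        x1, x2 = example.x, example.x_alt
        m = 0.3
        lhs = interpolate_features(x1, x2, m).data + interpolate_features(x2, x1, m).data
        np.testing.assert_allclose(lhs, x1.data + x2.data, atol=1e-9)

    def test_shape_mismatch_raises(self, example):
        small = FeatureTensor(np.zeros((1, 2, 2)), ["a"])
        with pytest.raises(ValueError):
            interpolate_features(example.x, small, 0.5)


class TestFlip:
    def test_involution(self, example):
        back = flip_example(flip_example(example))
        np.testing.assert_array_equal(back.x.data, example.x.data)
        np.testing.assert_array_equal(back.y, example.y)
        np.testing.assert_array_equal(back.loop_mask, example.loop_mask)

    def test_contact_moves_to_mirrored_index(self):
        L = 6
        y = np.zeros((L, L), dtype=np.int8)
        y[1, 4] = y[4, 1] = 1
        x = FeatureTensor(np.stack([separation_channel(L), np.ones((L, L))]), ["separation", "bounds"])
        ex = TrainingExample(x=x, y=y, loop_mask=np.zeros(L, dtype=bool))
        out = flip_example(ex)
        assert out.y[L - 2, L - 5] == 1 and out.y[L - 5, L - 2] == 1
        assert out.y.sum() == 2

    def test_separation_and_bounds_invariant(self, example):
        out = flip_example(example)
        np.testing.assert_array_equal(out.x.channel("separation"), example.x.channel("separation"))
        np.testing.assert_array_equal(out.x.channel("bounds"), example.x.channel("bounds"))


class TestAugmentBatch:
    def test_flip_doubles_batch(self, example):
        cfg = AugmentConfig(p_loop_apply=0.0, p_flip=1.0, p_mixup=0.0)
        out = augment_batch([clone(example) for _ in range(3)], cfg, np.random.default_rng(0))
        assert len(out) == 6
        np.testing.assert_array_equal(out[3].y, out[0].y[::-1, ::-1])

    def test_all_probabilities_zero_is_identity(self, example):
        cfg = AugmentConfig.disabled()
        batch = [example]
        out = augment_batch(batch, cfg, np.random.default_rng(0))
        assert out[0] is example and len(out) == 1

    def test_reproducible_given_seed(self, example):
        cfg = AugmentConfig(p_loop_apply=0.5, p_residue_del=0.3, p_flip=0.5)
        a = augment_batch([clone(example)] * 4, cfg, np.random.default_rng(77))
        b = augment_batch([clone(example)] * 4, cfg, np.random.default_rng(77))
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.x.data, eb.x.data)
            np.testing.assert_array_equal(ea.y, eb.y)

    def test_mixup_uses_paired_tensor(self, example):
        cfg = AugmentConfig(p_loop_apply=0.0, p_flip=0.0, p_mixup=1.0)
        out = augment_batch([clone(example)], cfg, np.random.default_rng(3))[0]
        # result is strictly between the two tensors somewhere
        assert not np.array_equal(out.x.data, example.x.data)
        np.testing.assert_array_equal(out.y, example.y)  # target never interpolated

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            augment_batch([], AugmentConfig(), np.random.default_rng(0))
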