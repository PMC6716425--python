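"""Segmentation loss oracles, network contracts, training behaviour."""

import numpy as np
import pytest

from pdstriatum.core import SAR_LABELS, LabelMap
from pdstriatum.nn import Tensor
from pdstriatum.phantom import generate_subject, segmentation_phantom_config
from pdstriatum.segmentation import (
    LossConfig,
    SegNetConfig,
    build_network,
    composite_loss,
    dice_per_label,
    evaluate_dsc,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)

RNG = np.random.default_rng(11)


def one_hot(truth, n_labels):
    probs = np.zeros((n_labels,) + truth.shape)
    for i in range(n_labels):
        probs[i] = truth == i
    return probs


class TestDicePerLabel:
    def test_perfect_overlap_is_one(self):
        truth = RNG.integers(0, 3, (4, 4, 4))
        assert dice_per_label(one_hot(truth, 3), truth, 1) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_nonempty_is_zero(self):
        truth = np.zeros((2, 2, 2), dtype=int)
        truth[0, 0, 0] = 1
        probs = np.zeros((2, 2, 2, 2))
        probs[1, 1, 1, 1] = 1.0   # label-1 mass somewhere else entirely
        assert dice_per_label(probs, truth, 1) == pytest.approx(0.0, abs=1e-6)

    def test_partial_overlap_matches_direct_summation(self):
        """4 truth voxels, unit probability on exactly 2 -> 2*2/(4+2)."""
        truth = np.zeros((2, 2, 2), dtype=int)
        truth.flat[:4] = 1
        probs = np.zeros((2, 2, 2, 2))
        probs[1].flat[:2] = 1.0
        assert dice_per_label(probs, truth, 1) == pytest.approx(2 / 3, abs=1e-6)

    def test_invariant_under_joint_voxel_permutation(self):
        truth = RNG.integers(0, 4, (3, 3, 3))
        probs = RNG.dirichlet(np.ones(4), size=truth.size).T.reshape(4, 3, 3, 3)
        perm = RNG.permutation(truth.size)
        truth_p = truth.ravel()[perm].reshape(truth.shape)
        probs_p = probs.reshape(4, -1)[:, perm].reshape(probs.shape)
        for lab in range(4):
            assert dice_per_label(probs, truth, lab) == pytest.approx(
                dice_per_label(probs_p, truth_p, lab), rel=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            dice_per_label(np.zeros((2, 3, 3, 3)), np.zeros((4, 4, 4)), 0)


def equal_dice_construction(n_labels=4, block=8):
    """Equal-count labels with p = e^-1 on the true label and the remaining
    mass uniform: every per-label soft Dice and every p_l(x) equals e^-1."""
    truth = np.repeat(np.arange(n_labels), block).reshape(2, -1, 2)
    probs = np.full((n_labels,) + truth.shape, (1 - np.exp(-1)) / (n_labels - 1))
    for i in range(n_labels):
        probs[i][truth == i] = np.exp(-1)
    return probs, truth


class TestCompositeLoss:
    def test_zero_on_perfect_one_hot(self):
        truth = RNG.integers(0, 3, (4, 4, 4))
        assert composite_loss(one_hot(truth, 3), truth) == pytest.approx(0.0, abs=1e-9)

    def test_unit_value_at_exp_minus_one_point(self):
        """With every Dice_i = e^-1 and every p_l(x) = e^-1 and weights
        (0.8, 0.2, 0.3): 0.8 * 1^0.3 + 0.2 * 1 = 1."""
        probs, truth = equal_dice_construction()
        cfg = LossConfig(w_D=0.8, w_C=0.2, gamma=0.3, include_background=True)
        assert composite_loss(probs, truth, cfg) == pytest.approx(1.0, abs=1e-5)

    def test_linear_in_weights(self):
        truth = RNG.integers(0, 3, (4, 4, 4))
        probs = RNG.dirichlet(np.ones(3), size=truth.size).T.reshape(3, 4, 4, 4)
        base = composite_loss(probs, truth, LossConfig(0.8, 0.2, 0.3))
        double = composite_loss(probs, truth, LossConfig(1.6, 0.4, 0.3))
        assert double == pytest.approx(2 * base, rel=1e-12)

    def test_nonnegative_and_finite_on_collapsed_predictions(self):
        truth = np.ones((3, 3, 3), dtype=int)
        probs = np.zeros((2, 3, 3, 3))
        probs[0] = 1.0   # everything predicted background
        val = composite_loss(probs, truth)
        assert np.isfinite(val) and val > 0

    def test_gradient_matches_finite_differences(self):
        """Analytic gradient of the composite loss in the probabilities vs
        central differences, within 1e-4 relative error."""
        x0 = RNG.uniform(0.05, 1.0, (3, 4, 4, 4))
        truth = RNG.integers(0, 3, (4, 4, 4))
        cfg = LossConfig()
        t = Tensor(x0, requires_grad=True)
        composite_loss(t, truth, cfg).backward()
        analytic = t.grad
        eps = 1e-6
        flat_idx = RNG.choice(x0.size, 25, replace=False)
        for fi in flat_idx:
            ix = np.unravel_index(fi, x0.shape)
            xp, xm = x0.copy(), x0.copy()
            xp[ix] += eps
            xm[ix] -= eps
            fd = (composite_loss(xp, truth, cfg) - composite_loss(xm, truth, cfg)) / (2 * eps)
            assert analytic[ix] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_loss_config_validation(self):
        with pytest.raises(ValueError):
            LossConfig(w_D=-0.1)
        with pytest.raises(ValueError):
            LossConfig(w_D=0.0, w_C=0.0)
        with pytest.raises(ValueError):
            LossConfig(gamma=0.0)


class TestNetwork:
    def test_output_shape_and_normalization(self):
        cfg = SegNetConfig(block_specs=((3, 1, 0.0), (5, 1, 0.0)), n_labels=4,
                           input_roi=(8, 8, 8))
        net = build_network(cfg, seed=0)
        probs = net.forward(RNG.normal(size=(8, 8, 8)))[0].data
        assert probs.shape == (4, 8, 8, 8)
        assert np.allclose(probs.sum(axis=0), 1.0)
        assert np.all(np.isfinite(probs)) and np.all(probs >= 0)

    def test_parameter_count_grows_with_width(self):
        small = build_network(SegNetConfig(block_specs=((3, 1, 0.0), (5, 1, 0.0)),
                                           input_roi=(8, 8, 8)))
        wide = build_network(SegNetConfig(block_specs=((6, 1, 0.0), (5, 1, 0.0)),
                                          input_roi=(8, 8, 8)))
        assert wide.n_parameters() > small.n_parameters()

    def test_roi_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            SegNetConfig(block_specs=((2, 1, 0.0),) * 3, input_roi=(30, 32, 32))

    def test_supervision_weights_normalized(self):
        cfg = SegNetConfig(block_specs=((2, 1, 0.0),) * 3, input_roi=(32, 32, 32))
        w = cfg.supervision_weights()
        assert w.sum() == pytest.approx(1.0) and w[0] > w[1]


@pytest.fixture(scope="module")
def tiny_setup():
    cfg = segmentation_phantom_config(noise_sd=0.0, geometry_jitter_sd=0.0, seed=3)
    subj = generate_subject(cfg, "NL", "tiny")
    # nonzero dropout on the first level so the stochastic path is
    # exercised when augmentation is on
    net_cfg = SegNetConfig(block_specs=((4, 1, 0.1), (8, 1, 0.0)),
                           input_roi=(16, 16, 16))
    return subj, net_cfg


class TestTraining:

    def test_zero_learning_rate_freezes_loss(self, tiny_setup):
        subj, net_cfg = tiny_setup
        net = build_network(net_cfg, seed=0)
        _, traj = train(net, [subj], net_cfg, LossConfig(), epochs=3, lr=0.0,
                        seed=0, augment=False)
        assert np.ptp(traj) == pytest.approx(0.0, abs=1e-6)

    def test_same_seed_reproduces_trajectory(self, tiny_setup):
        subj, net_cfg = tiny_setup
        trajs = []
        for _ in range(2):
            net = build_network(net_cfg, seed=5)
            _, traj = train(net, [subj], net_cfg, LossConfig(), epochs=3, lr=1e-3,
                            seed=5, augment=True)
            trajs.append(traj)
        assert trajs[0] == trajs[1]

    def test_loss_decreases_on_memorizable_instance(self, tiny_setup):
        subj, net_cfg = tiny_setup
        net = build_network(net_cfg, seed=1)
        _, traj = train(net, [subj], net_cfg, LossConfig(), epochs=12, lr=2e-3,
                        seed=1, augment=False)
        assert traj[-1] < traj[0]
        # near-monotone trend: each quarter-mean no worse than the previous
        quarters = [np.mean(traj[i:i + 3]) for i in range(0, 12, 3)]
        assert all(b <= a + 1e-6 for a, b in zip(quarters, quarters[1:]))

    def test_no_labeled_voxels_rejected(self, tiny_setup):
        subj, net_cfg = tiny_setup
        import copy

        bad = copy.deepcopy(subj)
        bad.labels_mr_space.data[:] = 0
        net = build_network(net_cfg, seed=0)
        with pytest.raises(ValueError, match="no labeled voxels"):
            train(net, [bad], net_cfg, LossConfig(), epochs=1)


class TestPredict:
    def test_overfit_training_subject_dice_above_09(self, overfit):
        assert min(overfit["dice"].values()) > 0.9

    def test_output_labels_within_dictionary(self, overfit):
        pred = predict(overfit["net"], overfit["subject"].mr)
        assert set(np.unique(pred.data)) <= set(range(7))

    def test_uniform_network_ties_break_to_lowest_label(self):
        cfg = SegNetConfig(block_specs=((2, 1, 0.0), (3, 1, 0.0)), n_labels=4,
                           input_roi=(8, 8, 8))
        net = build_network(cfg, seed=0)
        for w, b in net.heads:        # zero the heads: all logits equal
            w.data[:] = 0
            b.data[:] = 0
        from pdstriatum.core import ImageVolume

        vol = ImageVolume(RNG.normal(size=(8, 8, 8)), (1, 1, 1), (0, 0, 0))
        pred = predict(net, vol)
        assert np.all(pred.data == 0)

    def test_roi_larger_than_volume_errors_with_axis(self):
        from pdstriatum.core import ImageVolume

        cfg = SegNetConfig(block_specs=((2, 1, 0.0), (3, 1, 0.0)), input_roi=(8, 8, 8))
        net = build_network(cfg, seed=0)
        vol = ImageVolume(np.zeros((8, 6, 8)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="axis 1"):
            predict(net, vol)


class TestEvaluateDsc:
    def grid(self, data):
        return LabelMap(np.asarray(data, dtype=np.int32), (1, 1, 1), (0, 0, 0),
                        dict(r_putamen=SAR_LABELS["r_putamen"]))

    def test_identical_maps_score_one(self):
        data = np.zeros((4, 4, 4), dtype=np.int32)
        data[1:3] = SAR_LABELS["r_putamen"]
        assert evaluate_dsc(self.grid(data), self.grid(data),
                            {"r_putamen": SAR_LABELS["r_putamen"]}) == {"r_putamen": 1.0}

    def test_all_background_prediction_scores_zero(self):
        truth = np.zeros((4, 4, 4), dtype=np.int32)
        truth[1:3] = SAR_LABELS["r_putamen"]
        pred = np.zeros_like(truth)
        out = evaluate_dsc(self.grid(pred), self.grid(truth),
                           {"r_putamen": SAR_LABELS["r_putamen"]})
        assert out["r_putamen"] == 0.0

    def test_half_eroded_slab_by_voxel_count(self):
        """Truth: 4x4x2 slab (32 voxels); prediction keeps one layer (16):
        DSC = 2*16 / (32+16) = 2/3."""
        truth = np.zeros((4, 4, 4), dtype=np.int32)
        truth[:, :, 1:3] = SAR_LABELS["r_putamen"]
        pred = np.zeros_like(truth)
        pred[:, :, 1] = SAR_LABELS["r_putamen"]
        out = evaluate_dsc(self.grid(pred), self.grid(truth),
                           {"r_putamen": SAR_LABELS["r_putamen"]})
        assert out["r_putamen"] == pytest.approx(2 / 3)

    def test_cohort_mode_returns_mean_sd(self):
        truth = np.zeros((4, 4, 4), dtype=np.int32)
        truth[1:3] = SAR_LABELS["r_putamen"]
        pair = self.grid(truth)
        out = evaluate_dsc([pair, pair], [pair, pair],
                           {"r_putamen": SAR_LABELS["r_putamen"]})
        assert out["r_putamen"] == (1.0, 0.0)

    def test_mismatched_grids_rejected(self):
        a = self.grid(np.zeros((4, 4, 4), dtype=np.int32))
        b = self.grid(np.zeros((5, 4, 4), dtype=np.int32))
        with pytest.raises(ValueError):
            evaluate_dsc(a, b)


def test_checkpoint_round_trip(tmp_path, overfit):
    path = tmp_path / "net.npz"
    save_checkpoint(overfit["net"], path)
    loaded = load_checkpoint(path)
    mr = overfit["subject"].mr
    assert np.array_equal(predict(loaded, mr).data, predict(overfit["net"], mr).data)
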