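"""Deeply supervised residual 3D encoder-decoder for striatal segmentation.

The network maps a single-channel MR region of interest to per-voxel
probabilities over background + the six striatal anatomical regions. It is
trained with a composite loss

    L = w_D * E_i[(-ln Dice_i)^gamma] + w_C * E_x[-ln p_l(x)]

that combines an exponentiated negative-log soft-Dice term (which keeps small
structures from being swamped by background) with voxelwise cross-entropy.
Auxiliary softmax heads at the intermediate decoder resolutions receive the
same loss against downsampled truth ("deep supervision") for faster
convergence. Everything runs on the numpy autodiff engine in :mod:`.nn`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import center_of_mass, gaussian_filter

from .core import ImageVolume, LabelMap, SAR_LABELS
from .nn import (Adam, Tensor, concat, conv3d, default_dtype, dropout, maxpool2,
                 softmax_channels, upsample2)

_DICE_EPS = 1e-6      # smoothing in the soft-Dice ratio
# Underflow guards inside logarithms. They must stay far below any reachable
# probability, otherwise the clamp silences the gradient that rescues a
# collapsed class: softmax keeps p above the guard whenever logit gaps stay
# moderate, so the clamp only ever fires on hard numerical underflow.
_LOG_EPS = {np.dtype(np.float64): 1e-300, np.dtype(np.float32): 1e-30}
_POW_FLOOR = 1e-6     # gradient floor for the fractional power at Dice -> 1


@dataclass
class LossConfig:
    """Weights of the composite segmentation loss."""

    w_D: float = 0.8
    w_C: float = 0.2
    gamma: float = 0.3
    include_background: bool = False

    def __post_init__(self):
        if self.w_D < 0 or self.w_C < 0 or self.w_D + self.w_C <= 0:
            raise ValueError("loss weights must be non-negative with positive sum")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class SegNetConfig:
    """Architecture hyperparameters.

    ``block_specs`` lists one (n, k, r) triple per resolution level: channel
    count, number of convolution layers in the residual block, and dropout
    probability after the block. ``input_roi`` defaults to a desk-scale 32^3
    crop; 96^3 is the full-scale setting for clinical-resolution MR.
    """

    block_specs: tuple = ((8, 2, 0.0), (16, 2, 0.0), (32, 2, 0.0))
    n_labels: int = 7
    input_roi: tuple = (32, 32, 32)
    deep_supervision_weights: tuple | None = None
    blur_sd: float = 0.5

    @property
    def depth(self) -> int:
        return len(self.block_specs)

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        for n, k, r in self.block_specs:
            if not 0.0 <= r <= 1.0:
                raise ValueError("dropout probability must be in [0, 1]")
        div = 2 ** (self.depth - 1)
        if any(s % div for s in self.input_roi):
            raise ValueError(f"input_roi {self.input_roi} must be divisible by {div}")
        if self.deep_supervision_weights is not None:
            w = np.asarray(self.deep_supervision_weights, dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("deep_supervision_weights must be non-negative, one positive")

    def supervision_weights(self) -> np.ndarray:
        """Per-decoder-level loss weights (level 0 = full resolution),
        normalized to sum 1; default halves the weight per coarser level."""
        if self.deep_supervision_weights is not None:
            w = np.asarray(self.deep_supervision_weights, dtype=float)
        else:
            w = np.array([1.0 / 2 ** lvl for lvl in range(self.depth - 1)])
        return w / w.sum()


# ---------------------------------------------------------------------------
# Loss

def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _pow_safe(x: Tensor, exponent: float, floor: float = _POW_FLOOR) -> Tensor:
    """x**exponent with the backward base floored at ``floor`` so that
    fractional exponents keep finite gradients as x -> 0."""
    base = np.maximum(x.data, 0.0)

    def bw(g):
        if x.requires_grad:
            x.grad += g * exponent * np.power(np.maximum(base, floor), exponent - 1.0)

    return Tensor._make(np.power(base, exponent), (x,), bw)


def dice_per_label(probs, truth, label: int) -> float:
    """Soft Dice of one label: 2 * sum(delta * p) / sum(delta + p), where
    delta is the indicator of the ground-truth label and p the predicted
    probability field for that label (no thresholding). Smoothed by a small
    epsilon so an absent label with zero predicted mass scores 1."""
    probs = np.asarray(probs, dtype=np.float64)
    truth = np.asarray(truth)
    if probs.shape[1:] != truth.shape:
        raise ValueError("probs and truth must share the voxel grid")
    delta = (truth == label).astype(np.float64)
    p = probs[label]
    num = 2.0 * (delta * p).sum() + _DICE_EPS
    den = delta.sum() + p.sum() + _DICE_EPS
    return float(num / den)


def composite_loss(probs, truth, cfg: LossConfig = LossConfig()):
    """Composite Dice + cross-entropy loss.

    ``probs`` may be a numpy array (returns float) or an autodiff Tensor
    (returns a Tensor differentiable in the probabilities); shape
    (n_labels, D, H, W). ``truth`` is an integer label volume.
    """
    p, was_tensor = _as_tensor(probs)
    truth = np.asarray(truth)
    n_labels = p.data.shape[0]
    labels = range(0 if cfg.include_background else 1, n_labels)

    l_dice = _dice_loss(p, truth, labels, cfg.gamma)
    l_cross = _cross_entropy(p, truth)
    total = cfg.w_D * l_dice + cfg.w_C * l_cross
    return total if was_tensor else float(total.data)


def _channel(p: Tensor, i: int) -> Tensor:
    def bw(g):
        if p.requires_grad:
            p.grad[i] += g

    return Tensor._make(p.data[i], (p,), bw)


def _dice_loss(p: Tensor, truth: np.ndarray, labels, gamma: float) -> Tensor:
    terms = []
    for i in labels:
        delta = (truth == i).astype(np.float64)
        pi = _channel(p, i)
        inter = (pi * Tensor(delta)).sum()
        dice = (2.0 * inter + _DICE_EPS) / (Tensor(delta.sum()) + pi.sum() + _DICE_EPS)
        neglog = -(dice.clamp_min(_LOG_EPS[p.data.dtype]).log())
        terms.append(_pow_safe(neglog, gamma))
    acc = terms[0]
    for t in terms[1:]:
        acc = acc + t
    return acc * (1.0 / len(terms))


def _cross_entropy(p: Tensor, truth: np.ndarray) -> Tensor:
    onehot = np.zeros(p.data.shape, dtype=np.float64)
    for i in range(p.data.shape[0]):
        onehot[i] = truth == i
    p_true = (p * Tensor(onehot)).sum(axis=0)
    return -(p_true.clamp_min(_LOG_EPS[p.data.dtype]).log()).mean()


# ---------------------------------------------------------------------------
# Network

class _ResBlock:
    """k conv(3^3) + instance-norm + ReLU layers with an identity shortcut
    (1^3 projection when channel counts differ); dropout after the block."""

    def __init__(self, in_ch: int, n: int, k: int, r: float, rng: np.random.Generator):
        self.r = r
        self.convs = []
        ch = in_ch
        for _ in range(max(1, k)):
            fan_in = ch * 27
            w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), (n, ch, 3, 3, 3)), requires_grad=True)
            b = Tensor(np.zeros(n), requires_grad=True)
            gamma = Tensor(np.ones((n, 1, 1, 1)), requires_grad=True)
            beta = Tensor(np.zeros((n, 1, 1, 1)), requires_grad=True)
            self.convs.append((w, b, gamma, beta))
            ch = n
        if in_ch != n:
            self.proj = Tensor(rng.normal(0.0, np.sqrt(2.0 / in_ch), (n, in_ch, 1, 1, 1)),
                               requires_grad=True)
        else:
            self.proj = None

    def parameters(self):
        for w, b, g, bt in self.convs:
            yield from (w, b, g, bt)
        if self.proj is not None:
            yield self.proj

    @staticmethod
    def _instance_norm(x: Tensor, gamma: Tensor, beta: Tensor) -> Tensor:
        m = x.mean(axis=(1, 2, 3), keepdims=True)
        xm = x - m
        var = (xm * xm).mean(axis=(1, 2, 3), keepdims=True)
        return xm * (var + 1e-5).pow(-0.5) * gamma + beta

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        shortcut = x if self.proj is None else conv3d(x, self.proj)
        h = x
        for w, b, gamma, beta in self.convs:
            h = conv3d(h, w, b)
            h = self._instance_norm(h, gamma, beta)
            h = h.relu()
        out = h + shortcut
        if training and self.r > 0:
            out = dropout(out, self.r, rng)
        return out


class SegNet:
    """Residual 3D U-Net with deep supervision heads.

    ``forward`` returns the list of per-level softmax probability fields,
    index 0 at full resolution (the main output), index l at 1/2^l.
    """

    def __init__(self, cfg: SegNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        specs = cfg.block_specs
        self.enc = []
        ch = 1
        for n, k, r in specs:
            self.enc.append(_ResBlock(ch, n, k, r, rng))
            ch = n
        self.dec = []
        self.heads = []
        for lvl in range(cfg.depth - 2, -1, -1):
            n, k, r = specs[lvl]
            in_ch = ch + n  # upsampled deeper features + skip connection
            self.dec.append(_ResBlock(in_ch, n, k, r, rng))
            head = Tensor(rng.normal(0.0, np.sqrt(2.0 / n), (cfg.n_labels, n, 1, 1, 1)),
                          requires_grad=True)
            head_b = Tensor(np.zeros(cfg.n_labels), requires_grad=True)
            self.heads.append((head, head_b))
            ch = n
        self._rng = np.random.default_rng(seed + 1)

    def parameters(self):
        for blk in self.enc + self.dec:
            yield from blk.parameters()
        for w, b in self.heads:
            yield from (w, b)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(self, roi: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> list[Tensor]:
        rng = rng if rng is not None else self._rng
        x = Tensor(roi[None])   # coerced to the active default dtype
        skips = []
        for lvl, blk in enumerate(self.enc):
            x = blk(x, training, rng)
            if lvl < self.cfg.depth - 1:
                skips.append(x)
                x = maxpool2(x)
        outputs = {}
        for j, blk in enumerate(self.dec):
            lvl = self.cfg.depth - 2 - j
            x = upsample2(x)
            x = concat([x, skips[lvl]], axis=0)
            x = blk(x, training, rng)
            w, b = self.heads[j]
            outputs[lvl] = softmax_channels(conv3d(x, w, b))
        return [outputs[lvl] for lvl in range(self.cfg.depth - 1)]


def build_network(cfg: SegNetConfig, seed: int = 0) -> SegNet:
    """Construct the deeply supervised segmentation network."""
    return SegNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# Training and inference

def _roi_slices(center_vox, roi_shape, vol_shape):
    slices = []
    for ax, (c, r, s) in enumerate(zip(center_vox, roi_shape, vol_shape)):
        if r > s:
            raise ValueError(f"ROI of size {r} does not fit inside the volume "
                             f"on axis {ax} (volume size {s})")
        lo = min(max(int(round(c)) - r // 2, 0), s - r)  # shift crop to stay in bounds
        slices.append(slice(lo, lo + r))
    return tuple(slices)


def _normalize(roi: np.ndarray) -> np.ndarray:
    sd = roi.std()
    return (roi - roi.mean()) / (sd if sd > 0 else 1.0)


def _truth_for_net(labels: np.ndarray, n_labels: int) -> np.ndarray:
    """Map labels outside the network's class range (e.g. the occipital
    reference) to background."""
    return np.where(labels < n_labels, labels, 0).astype(np.int32)


def train(network: SegNet, subjects, cfg: SegNetConfig, loss_cfg: LossConfig,
          epochs: int = 10, lr: float = 1e-3, seed: int = 0, augment: bool = True,
          dtype: str = "float32"):
    """Train with Adam; returns (network, per-epoch mean loss trajectory).

    ROI crops are centred on the gold-label centroid. Gaussian-blur input
    augmentation is applied with probability 1/2 (SD from the config);
    ``augment=False`` disables both blur and dropout for strictly
    deterministic loss trajectories. Training runs in float32 by default
    (about twice as fast); parameters are returned as float64 either way.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    subjects = list(subjects)
    if not subjects:
        raise ValueError("no training subjects")
    rng = np.random.default_rng(seed)
    dt = np.dtype(dtype)
    ds_weights = cfg.supervision_weights()
    trajectory = []
    try:
        with default_dtype(dt):
            for p in network.parameters():
                p.data = p.data.astype(dt)
            opt = Adam(network.parameters(), lr=lr)
            for _ in range(epochs):
                order = rng.permutation(len(subjects))
                epoch_losses = []
                for idx in order:
                    subj = subjects[idx]
                    labels = subj.labels_mr_space.data
                    truth_full = _truth_for_net(labels, cfg.n_labels)
                    if not (truth_full > 0).any():
                        raise ValueError(f"subject {subj.id}: no labeled voxels for training")
                    centroid = center_of_mass(truth_full > 0)
                    sl = _roi_slices(centroid, cfg.input_roi, subj.mr.shape)
                    roi = _normalize(subj.mr.data[sl])
                    truth = truth_full[sl]
                    if augment and cfg.blur_sd > 0 and rng.random() < 0.5:
                        roi = gaussian_filter(roi, cfg.blur_sd)
                    probs_levels = network.forward(roi, training=augment, rng=rng)
                    total = None
                    for lvl, probs in enumerate(probs_levels):
                        stride = 2 ** lvl
                        t = truth[::stride, ::stride, ::stride]
                        term = composite_loss(probs, t, loss_cfg) * ds_weights[lvl]
                        total = term if total is None else total + term
                    opt.zero_grad()
                    total.backward()
                    opt.step()
                    epoch_losses.append(float(total.data))
                trajectory.append(float(np.mean(epoch_losses)))
    finally:
        for p in network.parameters():
            p.data = p.data.astype(np.float64)
    return network, trajectory


def train_to_convergence(network: SegNet, subjects, cfg: SegNetConfig,
                         loss_cfg: LossConfig, seed: int = 0,
                         warmup_epochs: int = 60, warmup_lr: float = 2e-3,
                         refine_epochs: int = 50, refine_lr: float = 5e-4,
                         max_refine_rounds: int = 5, target_dice: float = 0.92,
                         augment: bool = False):
    """Warmup + refinement schedule that stops once the network fits its
    training subjects (min per-SAR hard Dice above ``target_dice``) or the
    round cap is reached. Returns (network, trajectory, fitted_dice)."""
    network, traj = train(network, subjects, cfg, loss_cfg, epochs=warmup_epochs,
                          lr=warmup_lr, seed=seed, augment=augment)

    def _fitted_dice():
        worst = {}
        for subj in subjects:
            d = evaluate_dsc(predict(network, subj.mr,
                                     center_of_mass(subj.labels_mr_space.data > 0)),
                             subj.labels_mr_space)
            for k, v in d.items():
                worst[k] = min(worst.get(k, 1.0), v)
        return worst

    dice = _fitted_dice()
    prev_min = min(dice.values())
    stalled = False
    for round_ in range(max_refine_rounds):
        if prev_min > target_dice:
            break
        # cyclic restart: a stalled low-rate round gets kicked back to the
        # warmup rate to escape the plateau, then decays again
        lr = warmup_lr if stalled else refine_lr
        network, t = train(network, subjects, cfg, loss_cfg, epochs=refine_epochs,
                           lr=lr, seed=seed + 1 + round_, augment=augment)
        traj += t
        dice = _fitted_dice()
        new_min = min(dice.values())
        stalled = new_min < prev_min + 0.01
        prev_min = new_min
    return network, traj, dice


def predict(network: SegNet, mr: ImageVolume, roi_center=None) -> LabelMap:
    """Segment an MR volume: argmax over class probabilities inside the ROI
    (centred on the volume centre unless ``roi_center`` voxel indices are
    given), background elsewhere. Ties break to the lowest label index."""
    cfg = network.cfg
    if roi_center is None:
        roi_center = (np.asarray(mr.shape) - 1) / 2.0
    sl = _roi_slices(roi_center, cfg.input_roi, mr.shape)
    roi = _normalize(mr.data[sl])
    probs = network.forward(roi, training=False)[0].data
    pred = np.argmax(probs, axis=0).astype(np.int32)
    out = np.zeros(mr.shape, dtype=np.int32)
    out[sl] = pred
    return LabelMap(out, mr.spacing, mr.origin)


def evaluate_dsc(pred, truth, labels: dict[str, int] | None = None):
    """Hard (binarized) Dice per anatomical label.

    For one (pred, truth) pair returns {region: dsc}; for two equal-length
    lists returns {region: (mean, sd)} across subjects.
    """
    labels = labels or dict(SAR_LABELS)
    if isinstance(pred, (list, tuple)):
        per_subject = [evaluate_dsc(p, t, labels) for p, t in zip(pred, truth)]
        return {
            name: (float(np.mean([d[name] for d in per_subject])),
                   float(np.std([d[name] for d in per_subject])))
            for name in labels
        }
    if tuple(pred.shape) != tuple(truth.shape):
        raise ValueError("prediction and truth grids differ")
    out = {}
    for name, lab in labels.items():
        a = pred.data == lab
        b = truth.data == lab
        denom = a.sum() + b.sum()
        out[name] = float(2.0 * (a & b).sum() / denom) if denom else 1.0
    return out


# ---------------------------------------------------------------------------
# Checkpoints

def save_checkpoint(network: SegNet, path) -> None:
    """Single-file archive: parameter arrays plus the config as JSON."""
    arrays = {f"p{i}": p.data for i, p in enumerate(network.parameters())}
    cfg = network.cfg
    meta = json.dumps({
        "block_specs": [list(map(float, s)) for s in cfg.block_specs],
        "n_labels": cfg.n_labels,
        "input_roi": list(cfg.input_roi),
        "deep_supervision_weights": (None if cfg.deep_supervision_weights is None
                                     else list(cfg.deep_supervision_weights)),
        "blur_sd": cfg.blur_sd,
    })
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> SegNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        cfg = SegNetConfig(
            block_specs=tuple((int(n), int(k), float(r)) for n, k, r in meta["block_specs"]),
            n_labels=int(meta["n_labels"]),
            input_roi=tuple(meta["input_roi"]),
            deep_supervision_weights=(None if meta["deep_supervision_weights"] is None
                                      else tuple(meta["deep_supervision_weights"])),
            blur_sd=float(meta["blur_sd"]),
        )
        net = SegNet(cfg)
        for i, p in enumerate(net.parameters()):
            p.data = data[f"p{i}"].astype(np.float64)
    return net
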