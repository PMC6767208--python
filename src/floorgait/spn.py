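"""Step Proposal Network: a fully-convolutional 1D network that scores
anchor boxes for containing a footstep.

The first convolution (32 filters of size 60, stride 10) places the
feature map on a stride-10 grid; each grid position ``i`` carries three
anchor boxes of 20, 30 and 40 raw samples starting at sample ``10 i``
(typical step durations at 100 Hz).  Anchors with intersection-over-union
above 0.7 against any ground-truth step box are positive, below 0.3
negative, and all others neutral — neutral anchors contribute nothing to
the loss.  The trained network's three conv/batch-norm/tanh blocks are
later transferred (frozen) into the activity classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from floorgait import nn
from floorgait.dataset import StepBox
from floorgait.stepdict import EmbeddedSignal

__all__ = [
    "AnchorGrid",
    "iou",
    "box_iou",
    "assign_anchors",
    "StepProposalNetwork",
    "spn_forward",
    "spn_loss",
    "train_spn",
    "decode_boxes",
    "average_precision",
]

STRIDE = 10
KERNEL = 60
BOX_SIZES = (20, 30, 40)
IOU_HI = 0.7
IOU_LO = 0.3
EPS = 1e-7

POSITIVE = 1
NEUTRAL = 0
NEGATIVE = -1


@dataclass(frozen=True)
class AnchorGrid:
    """Anchor boxes on the stride-10 feature grid of an input of length T."""

    input_len: int
    stride: int = STRIDE
    box_sizes: tuple[int, ...] = BOX_SIZES
    kernel: int = KERNEL

    @property
    def feature_len(self) -> int:
        return (self.input_len - self.kernel) // self.stride + 1

    def anchor(self, i: int, k: int) -> StepBox:
        start = i * self.stride
        return StepBox(start, start + self.box_sizes[k])

    def all_anchors(self) -> np.ndarray:
        """(feature_len, n_sizes, 2) array of [start, end) pairs."""
        starts = np.arange(self.feature_len)[:, None] * self.stride
        sizes = np.asarray(self.box_sizes)[None, :]
        return np.stack([np.broadcast_to(starts, (self.feature_len, len(self.box_sizes))),
                         starts + sizes], axis=-1)


def box_iou(a: StepBox, b: StepBox) -> float:
    """Intersection-over-union of two half-open integer intervals."""
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = len(a) + len(b) - inter
    return inter / union


def iou(candidate: StepBox, ground_truth: list[StepBox]) -> float:
    """Best IoU of the candidate against any ground-truth box (0 if none)."""
    if not ground_truth:
        return 0.0
    return max(box_iou(candidate, g) for g in ground_truth)


def assign_anchors(
    grid: AnchorGrid,
    gt: list[StepBox],
    hi: float = IOU_HI,
    lo: float = IOU_LO,
) -> np.ndarray:
    """Label every anchor positive (+1), negative (-1) or neutral (0)."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    anchors = grid.all_anchors()  # (T_f, K, 2)
    if gt:
        g = np.asarray([[b.start, b.end] for b in gt])  # (G, 2)
        inter = np.maximum(
            0,
            np.minimum(anchors[..., 1, None], g[None, None, :, 1])
            - np.maximum(anchors[..., 0, None], g[None, None, :, 0]),
        )
        len_a = (anchors[..., 1] - anchors[..., 0])[..., None]
        len_g = (g[:, 1] - g[:, 0])[None, None, :]
        best = (inter / (len_a + len_g - inter)).max(axis=-1)
    else:
        best = np.zeros(anchors.shape[:2])
    labels = np.full(best.shape, NEUTRAL, dtype=np.int8)
    labels[best > hi] = POSITIVE
    labels[best < lo] = NEGATIVE
    return labels


class StepProposalNetwork:
    """Conv(3->32, k60, s10)+BN+tanh; two 1x1 conv+BN+tanh blocks (32->16,
    16->8); 1x1 conv(8->3)+sigmoid scoring the three anchor sizes.

    Dropout (p) after each batch-norm layer is active during training
    only.  ``blocks`` exposes the three conv/BN/tanh blocks transferred
    into the activity classifier.
    """

    def __init__(self, seed: int | None = None, dropout: float = 0.5,
                 init_std: float = nn.INIT_STD, in_channels: int = 3):
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.drop_layers = [nn.Dropout(dropout) for _ in range(3)]
        self.net = nn.Sequential(
            nn.Conv1d(in_channels, 32, KERNEL, STRIDE, rng=rng, init_std=init_std),
            nn.BatchNorm1d(32), nn.Tanh(), self.drop_layers[0],
            nn.Conv1d(32, 16, 1, rng=rng, init_std=init_std),
            nn.BatchNorm1d(16), nn.Tanh(), self.drop_layers[1],
            nn.Conv1d(16, 8, 1, rng=rng, init_std=init_std),
            nn.BatchNorm1d(8), nn.Tanh(), self.drop_layers[2],
            nn.Conv1d(8, 3, 1, rng=rng, init_std=init_std),
            nn.Sigmoid(),
        )
        self.net.set_rng(np.random.default_rng(None if seed is None else seed + 1))

    @property
    def blocks(self) -> list[nn.Layer]:
        """The three conv/BN/tanh blocks (without dropout), in order."""
        L = self.net.layers
        return [L[0], L[1], L[2], L[4], L[5], L[6], L[8], L[9], L[10]]

    def forward_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, C, T) -> (N, T_f, K) score maps."""
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels")
        if x.shape[2] < KERNEL:
            raise ValueError(f"input shorter than {KERNEL} samples")
        self.net.set_train(train)
        out = self.net.forward(x)  # (N, 3, T_f)
        return out.transpose(0, 2, 1)

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.net.state_dict()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state_dict(state)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, **kwargs) -> "StepProposalNetwork":
        spn = cls(seed=0, **kwargs)
        with np.load(path) as z:
            spn.load_state_dict(dict(z))
        return spn


def spn_forward(x: EmbeddedSignal | np.ndarray, net: StepProposalNetwork) -> np.ndarray:
    """Score map W (feature_len x 3, entries in (0,1)) for one signal."""
    arr = x.channels if isinstance(x, EmbeddedSignal) else np.atleast_2d(np.asarray(x))
    return net.forward_batch(arr[None, :, :], train=False)[0]


def spn_loss(w: np.ndarray, labels: np.ndarray) -> float:
    """Negated anchor log-likelihood: positives reward log W, negatives
    reward log(1 - W), neutral anchors contribute exactly zero."""
    loss, _ = spn_loss_grad(w, labels)
    return loss


def spn_loss_grad(w: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    if w.shape != labels.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {labels.shape}")
    wc = np.clip(w, EPS, 1.0 - EPS)
    pos = labels == POSITIVE
    neg = labels == NEGATIVE
    loss = -(np.sum(np.log(wc[pos])) + np.sum(np.log(1.0 - wc[neg])))
    grad = np.zeros_like(wc)
    grad[pos] = -1.0 / wc[pos]
    grad[neg] = 1.0 / (1.0 - wc[neg])
    return float(loss), grad


def _pad_to(x: np.ndarray, t: int) -> np.ndarray:
    if x.shape[-1] == t:
        return x
    out = np.zeros(x.shape[:-1] + (t,))
    out[..., : x.shape[-1]] = x
    return out


def train_spn(
    walks: list[tuple[EmbeddedSignal, list[StepBox]]],
    cfg: "nn_config.TrainConfig | None" = None,
    seed: int = 0,
) -> StepProposalNetwork:
    """Train the step-proposal network on embedded walks with step boxes.

    Signals without a single positive anchor are skipped with a warning.
    Training follows the shared recipe: SGD with Nesterov momentum,
    learning rate 1e-5 decaying x0.9 every 10 epochs, dropout 0.5 after
    each batch norm, early stopping on a held-out validation split.
    Deterministic given ``seed``.
    """
    from floorgait.train import TrainConfig

    cfg = cfg or TrainConfig()
    if not walks:
        raise ValueError("empty training set")
    t_max = max(len(e) for e, _ in walks)
    xs, labels = [], []
    for emb, boxes in walks:
        grid = AnchorGrid(t_max)
        lab = assign_anchors(grid, list(boxes))
        if not np.any(lab == POSITIVE):
            warnings.warn(f"signal {emb.source_id!r} has no positive anchor; skipped")
            continue
        xs.append(_pad_to(emb.channels, t_max))
        labels.append(lab)
    if not xs:
        raise ValueError("no training signal has a positive anchor")
    x = np.stack(xs)
    y = np.stack(labels)

    rng = np.random.default_rng(seed)
    net = StepProposalNetwork(seed=seed, dropout=cfg.dropout, init_std=cfg.init_std)
    net.net.set_rng(np.random.default_rng(rng.integers(2**31)))

    n = x.shape[0]
    n_val = max(int(round(cfg.val_fraction * n)), 1) if n >= 5 else 0
    order = rng.permutation(n)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if tr_idx.size == 0:
        tr_idx, val_idx = order, order[:0]

    def dataset_loss(idx: np.ndarray, train_mode: bool) -> float:
        if idx.size == 0:
            return np.nan
        w = net.forward_batch(x[idx], train=train_mode)
        return float(np.mean([spn_loss(w[i], y[idx][i]) for i in range(idx.size)]))

    opt = nn.SGD(net.net.params(), lr=cfg.lr, momentum=cfg.momentum)
    best_state = net.state_dict()
    best_val = dataset_loss(val_idx, False) if val_idx.size else dataset_loss(tr_idx, False)
    stale = 0
    for epoch in range(cfg.max_epochs):
        opt.lr = nn.lr_at_epoch(cfg.lr, epoch, cfg.lr_decay, cfg.lr_decay_every)
        perm = rng.permutation(tr_idx.size)
        for start in range(0, tr_idx.size, cfg.batch_size):
            idx = tr_idx[perm[start : start + cfg.batch_size]]
            w = net.forward_batch(x[idx], train=True)  # (B, T_f, K)
            grads = np.stack([spn_loss_grad(w[i], y[idx][i])[1] for i in range(idx.size)])
            net.net.zero_grad()
            net.net.backward(grads.transpose(0, 2, 1) / idx.size)
            opt.step()
        val = dataset_loss(val_idx, False) if val_idx.size else dataset_loss(tr_idx, False)
        if val < best_val - 1e-9:
            best_val = val
            best_state = net.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    net.load_state_dict(best_state)
    return net


def decode_boxes(
    w: np.ndarray,
    grid: AnchorGrid,
    score_min: float = 0.5,
    nms_iou: float = 0.5,
) -> list[tuple[StepBox, float]]:
    """Greedy non-maximum suppression over thresholded anchor scores."""
    if not (0.0 <= score_min <= 1.0 and 0.0 <= nms_iou <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    cands = [
        (float(w[i, k]), grid.anchor(i, k))
        for i in range(w.shape[0])
        for k in range(w.shape[1])
        if w[i, k] >= score_min
    ]
    cands.sort(key=lambda c: (-c[0], c[1].start, len(c[1])))
    kept: list[tuple[StepBox, float]] = []
    for score, box in cands:
        if all(box_iou(box, kb) <= nms_iou for kb, _ in kept):
            kept.append((box, score))
    return kept


def average_precision(
    predictions_per_signal: list[list[tuple[StepBox, float]]],
    gt_per_signal: list[list[StepBox]],
    iou_thresh: float,
) -> float:
    """All-point interpolated average precision.

    Predictions are pooled across signals and ranked by score; each is a
    true positive if it matches a still-unmatched ground-truth box of its
    own signal with IoU >= ``iou_thresh`` (greedy in score order).
    """
    if not 0.0 < iou_thresh <= 1.0:
        raise ValueError("iou_thresh must lie in (0, 1]")
    n_gt = sum(len(g) for g in gt_per_signal)
    if n_gt == 0:
        raise ValueError("no ground-truth boxes to evaluate against")
    pool = [
        (score, sig, box)
        for sig, preds in enumerate(predictions_per_signal)
        for box, score in preds
    ]
    pool.sort(key=lambda p: (-p[0], p[1], p[2].start))
    matched: list[set[int]] = [set() for _ in gt_per_signal]
    tp = np.zeros(len(pool))
    for rank, (_, sig, box) in enumerate(pool):
        gts = gt_per_signal[sig]
        best_j, best_v = -1, 0.0
        for j, g in enumerate(gts):
            if j in matched[sig]:
                continue
            v = box_iou(box, g)
            if v > best_v:
                best_j, best_v = j, v
        if best_j >= 0 and best_v >= iou_thresh:
            tp[rank] = 1.0
            matched[sig].add(best_j)
    if not pool:
        return 0.0
    cum_tp = np.cumsum(tp)
    precision = cum_tp / np.arange(1, len(pool) + 1)
    recall = cum_tp / n_gt
    # interpolate: precision at recall r is the max precision at recall >= r
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, p_interp):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)
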