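"""Staff-vs-elderly activity classifier.

The classifier reuses the three conv/batch-norm/tanh blocks of a trained
step-proposal network as a frozen feature extractor and adds a small
head: conv(8->1, kernel 5) + ReLU, maxpool(5), then dense 64 -> 16 -> 1
with a sigmoid output.  The output is read as the probability that the
recorded activity was produced by medical staff (label 1 = staff,
0 = elderly); an activity is classified as staff when the score reaches
the decision threshold tau.

Head weights start i.i.d. N(0, 0.2^2); training is SGD with Nesterov
momentum, binary cross entropy summed over the batch, dropout 0.5 after
each hidden dense layer, and early stopping.  Frozen blocks — weights
and batch-norm running statistics alike — never change.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np

from floorgait import nn
from floorgait.spn import KERNEL, STRIDE, StepProposalNetwork
from floorgait.stepdict import EmbeddedSignal
from floorgait.train import TrainConfig

__all__ = [
    "TrainConfig",
    "ActivityScore",
    "ActivityClassifier",
    "pad_or_crop",
    "bce_loss",
    "build_classifier",
    "train_classifier",
    "classify",
]

EPS = 1e-7
HEAD_CONV_KERNEL = 5
POOL_SIZE = 5


@dataclass
class ActivityScore:
    """Probability that the activity is staff, with a decision threshold."""

    y_hat: float
    tau: float = 0.5

    @property
    def is_staff(self) -> bool:
        return self.y_hat >= self.tau


def pad_or_crop(x: EmbeddedSignal | np.ndarray, target_len: int = 1000):
    """Fix the time length: symmetric zero padding for short signals,
    center cropping for long ones (extra sample goes to the right/end)."""
    if target_len < KERNEL:
        raise ValueError(f"target_len must be at least {KERNEL}")
    arr = x.channels if isinstance(x, EmbeddedSignal) else np.atleast_2d(np.asarray(x, dtype=float))
    t = arr.shape[-1]
    if t < target_len:
        left = (target_len - t) // 2
        out = np.zeros(arr.shape[:-1] + (target_len,))
        out[..., left : left + t] = arr
    elif t > target_len:
        left = (t - target_len) // 2
        out = arr[..., left : left + target_len]
    else:
        out = arr.copy()
    if isinstance(x, EmbeddedSignal):
        return EmbeddedSignal(out, rate_hz=x.rate_hz, source_id=x.source_id)
    return out


def bce_loss(y_hat, y) -> float:
    """Binary cross entropy, summed: -sum[y log yh + (1-y) log(1-yh)]."""
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.shape != y.shape:
        raise ValueError("y_hat and y must have equal length")
    yh = np.clip(y_hat, EPS, 1.0 - EPS)
    return float(-np.sum(y * np.log(yh) + (1.0 - y) * np.log(1.0 - yh)))


def _bce_grad(y_hat: np.ndarray, y: np.ndarray) -> np.ndarray:
    yh = np.clip(y_hat, EPS, 1.0 - EPS)
    return -(y / yh) + (1.0 - y) / (1.0 - yh)


class ActivityClassifier:
    """Frozen feature blocks (optionally transferred) plus trainable head."""

    def __init__(self, blocks: list[nn.Layer], head: nn.Sequential,
                 in_channels: int, input_len: int):
        self.blocks = blocks
        self.head = head
        self.in_channels = in_channels
        self.input_len = input_len
        self.net = nn.Sequential(*blocks, *head.layers)

    @staticmethod
    def head_feature_len(input_len: int) -> int:
        t1 = (input_len - KERNEL) // STRIDE + 1
        t_conv = t1 - HEAD_CONV_KERNEL + 1
        return t_conv // POOL_SIZE

    def forward_batch(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels or x.shape[2] != self.input_len:
            raise ValueError(
                f"expected input of shape (N, {self.in_channels}, {self.input_len})"
            )
        self.net.set_train(train)
        return self.net.forward(x).ravel()

    def score(self, x: EmbeddedSignal | np.ndarray, tau: float = 0.5) -> ActivityScore:
        arr = x.channels if isinstance(x, EmbeddedSignal) else np.atleast_2d(np.asarray(x))
        y = self.forward_batch(arr[None, :, :], train=False)
        return ActivityScore(float(y[0]), tau)

    def frozen_state(self) -> dict[str, np.ndarray]:
        """Snapshot of the frozen transferred blocks (params and BN stats)."""
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.blocks):
            if not layer.frozen:
                continue
            for j, p in enumerate(layer.params()):
                state[f"block{i}.param{j}"] = p.value.copy()
            for name, buf in layer.buffers().items():
                state[f"block{i}.{name}"] = buf.copy()
        return state

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.net.state_dict()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state_dict(state)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())


def _make_head(feat_len: int, rng: np.random.Generator, dropout: float,
               init_std: float) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv1d(8, 1, HEAD_CONV_KERNEL, 1, rng=rng, init_std=init_std),
        nn.ReLU(),
        nn.MaxPool1d(POOL_SIZE),
        nn.Flatten(),
        nn.Dense(feat_len, 64, rng=rng, init_std=init_std),
        nn.ReLU(),
        nn.Dropout(dropout),
        nn.Dense(64, 16, rng=rng, init_std=init_std),
        nn.ReLU(),
        nn.Dropout(dropout),
        nn.Dense(16, 1, rng=rng, init_std=init_std),
        nn.Sigmoid(),
    )


def build_classifier(
    spn: StepProposalNetwork | None,
    cfg: TrainConfig | None = None,
    seed: int = 0,
    in_channels: int = 3,
    freeze: bool = True,
) -> ActivityClassifier:
    """Assemble the classifier.

    With a trained step-proposal network the three feature blocks are
    copied over and (by default) frozen, batch-norm statistics included.
    With ``spn=None`` the blocks are freshly Gaussian-initialized and
    trainable — the from-scratch ablation variant.  The head is always
    newly initialized from ``seed``.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(seed)
    if spn is not None:
        source = copy.deepcopy(spn.blocks)
        if spn.in_channels != in_channels:
            raise ValueError("channel count mismatch with the transferred network")
        if freeze:
            for layer in source:
                layer.freeze()
        blocks = source
    else:
        fresh = StepProposalNetwork(seed=int(rng.integers(2**31)), dropout=0.0,
                                    init_std=cfg.init_std, in_channels=in_channels)
        blocks = fresh.blocks
    head = _make_head(ActivityClassifier.head_feature_len(cfg.input_len),
                      np.random.default_rng(int(rng.integers(2**31))),
                      cfg.dropout, cfg.init_std)
    clf = ActivityClassifier(blocks, head, in_channels, cfg.input_len)
    clf.net.set_rng(np.random.default_rng(int(rng.integers(2**31))))
    return clf


def train_classifier(
    data: list[tuple[EmbeddedSignal | np.ndarray, int]],
    clf: ActivityClassifier,
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> ActivityClassifier:
    """Train the classifier on (embedded signal, label) pairs, label 1 for
    staff and 0 for elderly.

    Frozen blocks are excluded from the optimizer and verified bitwise
    unchanged on return.  Early stopping keeps the weights of the best
    validation-loss epoch.  A single-class training set trains with a
    warning.
    """
    cfg = cfg or TrainConfig()
    if not data:
        raise ValueError("empty training set")
    xs = []
    for item, _ in data:
        arr = item.channels if isinstance(item, EmbeddedSignal) else np.atleast_2d(np.asarray(item))
        xs.append(pad_or_crop(arr, cfg.input_len))
    x = np.stack(xs)
    y = np.asarray([label for _, label in data], dtype=float)
    if len(np.unique(y)) < 2:
        warnings.warn("training set contains a single class")

    frozen_before = clf.frozen_state()
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    n_val = max(int(round(cfg.val_fraction * n)), 1) if n >= 5 else 0
    # stratified validation split: sample within each label
    val_idx_parts = []
    for label in np.unique(y):
        members = np.flatnonzero(y == label)
        k = max(int(round(cfg.val_fraction * members.size)), 1) if n_val else 0
        k = min(k, members.size - 1) if members.size > 1 else 0
        val_idx_parts.append(rng.permutation(members)[:k])
    val_idx = np.concatenate(val_idx_parts) if val_idx_parts else np.array([], dtype=int)
    tr_idx = np.setdiff1d(np.arange(n), val_idx)

    def dataset_loss(idx: np.ndarray) -> float:
        if idx.size == 0:
            return np.nan
        yh = clf.forward_batch(x[idx], train=False)
        return bce_loss(yh, y[idx]) / idx.size

    opt = nn.SGD(clf.net.params(), lr=cfg.lr, momentum=cfg.momentum)
    best_val = dataset_loss(val_idx) if val_idx.size else dataset_loss(tr_idx)
    best_state = clf.state_dict()
    stale = 0
    for epoch in range(cfg.max_epochs):
        opt.lr = nn.lr_at_epoch(cfg.lr, epoch, cfg.lr_decay, cfg.lr_decay_every)
        perm = rng.permutation(tr_idx.size)
        for start in range(0, tr_idx.size, cfg.batch_size):
            idx = tr_idx[perm[start : start + cfg.batch_size]]
            yh = clf.forward_batch(x[idx], train=True)
            grad = _bce_grad(yh, y[idx])
            clf.net.zero_grad()
            clf.net.backward(grad[:, None])
            opt.step()
        val = dataset_loss(val_idx) if val_idx.size else dataset_loss(tr_idx)
        if val < best_val - 1e-9:
            best_val, best_state, stale = val, clf.state_dict(), 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    clf.load_state_dict(best_state)

    frozen_after = clf.frozen_state()
    for key, before in frozen_before.items():
        if not np.array_equal(before, frozen_after[key]):
            raise AssertionError(f"frozen tensor {key} changed during training")
    return clf


def classify(scores: list[ActivityScore] | list[float], tau: float = 0.5) -> list[str]:
    """Threshold scores: staff iff y_hat >= tau (inclusive)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    out = []
    for s in scores:
        y = s.y_hat if isinstance(s, ActivityScore) else float(s)
        out.append("staff" if y >= tau else "elderly")
    return out
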