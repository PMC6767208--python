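"""Shared training configuration for the step-proposal network and the
activity classifier."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class TrainConfig:
    """SGD recipe shared by both networks.

    lr decays geometrically (``lr_decay`` every ``lr_decay_every`` epochs);
    momentum is Nesterov; weights start i.i.d. N(0, init_std^2); dropout is
    applied where each architecture prescribes it.  Early stopping watches
    a ``val_fraction`` split of the training set with the given patience.
    ``input_len`` is the canonical signal length in samples (10 s at
    100 Hz).
    """

    lr: float = 1e-5
    lr_decay: float = 0.9
    lr_decay_every: int = 10
    momentum: float = 0.99
    dropout: float = 0.5
    init_std: float = 0.2
    batch_size: int = 16
    patience: int = 20
    max_epochs: int = 500
    input_len: int = 1000
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        for name in ("lr", "lr_decay", "momentum", "init_std", "batch_size",
                     "patience", "max_epochs", "input_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
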