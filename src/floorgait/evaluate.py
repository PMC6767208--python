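"""Evaluation metrics and the ablation harness.

Metrics: ROC AUC (the probability that a random staff signal outscores a
random elderly signal), a stratified-bootstrap percentile confidence
interval for it, per-activity-label ROC curves, and threshold confusion
tables laid out by (true status x activity label).

The ablation harness runs the full pipeline and its reduced variants on
identical splits and seeds:

* ``full`` — dictionary embedding, step-proposal pretraining, frozen
  transfer;
* ``no_spn_pretrain`` — same architecture trained from scratch on the
  classification task (embedding kept);
* ``raw_cnn`` — no embedding, no pretraining: the CNN reads the
  preprocessed mono signal directly;
* ``rf_baseline`` — a random forest on the flattened embedded signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from floorgait.classifier import build_classifier, pad_or_crop, train_classifier
from floorgait.dataset import Dataset, PersonStatus, activity_group, stratified_split
from floorgait.preprocess import preprocess
from floorgait.spn import train_spn
from floorgait.stepdict import (
    StepDictionary,
    embed,
    learn_dictionary,
    walk_training_filter,
)
from floorgait.train import TrainConfig

__all__ = [
    "AblationVariant",
    "EvalReport",
    "roc_auc",
    "auc_ci",
    "confusion_at",
    "run_pipeline",
    "run_ablation",
]


class AblationVariant(str, Enum):
    FULL = "full"
    NO_SPN_PRETRAIN = "no_spn_pretrain"
    RAW_CNN = "raw_cnn"
    RF_BASELINE = "rf_baseline"


def roc_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability (ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auc_ci(scores, labels, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Percentile 2.5/97.5 stratified-bootstrap interval for the AUC."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels != 1)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)])
        stats[b] = roc_auc_score(labels[idx], scores[idx])
    low, high = np.percentile(stats, [2.5, 97.5])
    return float(low), float(high)


def confusion_at(scores, labels, strata, tau: float) -> dict:
    """Confusion table at threshold tau.

    Keys are (true status, activity label) pairs; values are
    ``{"classified_staff": n, "classified_elderly": n}`` using the
    inclusive >= tau rule.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    table: dict = {}
    for s, y, stratum in zip(scores, labels, strata):
        status = "staff" if y == 1 else "elderly"
        cell = table.setdefault((status, stratum),
                                {"classified_staff": 0, "classified_elderly": 0})
        cell["classified_staff" if s >= tau else "classified_elderly"] += 1
    return table


@dataclass
class EvalReport:
    auc: float
    auc_ci: tuple[float, float]
    n: int
    per_label_roc: dict = field(default_factory=dict)
    confusions: dict = field(default_factory=dict)
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None
    strata: list | None = None


def _report(scores, labels, strata, taus=(0.2, 0.4), n_boot=500, seed=0) -> EvalReport:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    per_label = {}
    for group in sorted(set(strata)):
        mask = np.asarray([s == group for s in strata])
        if len(np.unique(labels[mask])) == 2:
            fpr, tpr, _ = roc_curve(labels[mask], scores[mask])
            per_label[group] = {
                "auc": float(roc_auc_score(labels[mask], scores[mask])),
                "fpr": fpr.tolist(),
                "tpr": tpr.tolist(),
            }
    return EvalReport(
        auc=roc_auc(scores, labels),
        auc_ci=auc_ci(scores, labels, n_boot=n_boot, seed=seed),
        n=len(scores),
        per_label_roc=per_label,
        confusions={tau: confusion_at(scores, labels, strata, tau) for tau in taus},
        scores=scores,
        labels=labels,
        strata=list(strata),
    )


@dataclass
class PipelineConfig:
    """End-to-end settings: dictionary hyperparameters plus the network
    training recipe. Dictionary defaults follow the step-atom recipe
    (m=3 atoms of 0.7 s, lambda=5); ``dict_iters`` controls solver effort."""

    dict_m: int = 3
    dict_atom_sec: float = 0.7
    dict_lambda: float = 5.0
    dict_iters: int = 200
    test_fraction: float = 0.3
    rf_trees: int = 500
    train: TrainConfig = field(default_factory=TrainConfig)


def _labels_strata(ds: Dataset):
    labels = np.asarray(
        [1 if r.annotation.person_status is PersonStatus.STAFF else 0 for r in ds]
    )
    strata = [activity_group(r.annotation.event_class) for r in ds]
    return labels, strata


def run_pipeline(
    variant: AblationVariant | str,
    data: Dataset,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
):
    """Train one variant and score every signal.

    Returns ``(test_report, all_report, aux)`` where ``aux`` holds the
    trained artifacts (dictionary, networks) for reuse.
    """
    variant = AblationVariant(variant)
    cfg = cfg or PipelineConfig()
    train_ds, test_ds = stratified_split(data, cfg.test_fraction, seed)

    monos = {r.id: preprocess(r) for r in data}
    aux: dict = {"train_ids": [r.id for r in train_ds], "test_ids": [r.id for r in test_ds]}

    if variant is AblationVariant.RAW_CNN:
        feats = {
            rid: pad_or_crop(m.s[None, :], cfg.train.input_len) for rid, m in monos.items()
        }
        in_channels = 1
    else:
        dict_train = [monos[r.id] for r in train_ds if walk_training_filter(r)]
        dictionary, _ = learn_dictionary(
            dict_train, m=cfg.dict_m, atom_sec=cfg.dict_atom_sec,
            lam=cfg.dict_lambda, iters=cfg.dict_iters, seed=seed,
        )
        aux["dictionary"] = dictionary
        feats = {
            rid: pad_or_crop(embed(m, dictionary).channels, cfg.train.input_len)
            for rid, m in monos.items()
        }
        in_channels = cfg.dict_m

    y_train, _ = _labels_strata(train_ds)

    if variant is AblationVariant.RF_BASELINE:
        rf = RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=seed)
        rf.fit(
            np.stack([feats[r.id].ravel() for r in train_ds]), y_train
        )
        aux["rf"] = rf

        def scorer(ds: Dataset) -> np.ndarray:
            x = np.stack([feats[r.id].ravel() for r in ds])
            return rf.predict_proba(x)[:, 1]

    else:
        spn_net = None
        if variant is AblationVariant.FULL:
            walk_recs = [r for r in train_ds.recordings if walk_training_filter(r)]
            spn_net = train_spn(
                [(embed(monos[r.id], aux["dictionary"]), r.annotation.step_boxes)
                 for r in walk_recs],
                cfg.train, seed=seed,
            )
            aux["spn"] = spn_net
        clf = build_classifier(
            spn_net, cfg.train, seed=seed, in_channels=in_channels,
            freeze=variant is AblationVariant.FULL,
        )
        pairs = [(feats[r.id], int(y)) for r, y in zip(train_ds.recordings, y_train)]
        clf = train_classifier(pairs, clf, cfg.train, seed=seed)
        aux["classifier"] = clf

        def scorer(ds: Dataset) -> np.ndarray:
            x = np.stack([feats[r.id] for r in ds])
            return clf.forward_batch(x, train=False)

    yt, st = _labels_strata(test_ds)
    ya, sa = _labels_strata(data)
    test_report = _report(scorer(test_ds), yt, st, seed=seed)
    all_report = _report(scorer(data), ya, sa, seed=seed)
    return test_report, all_report, aux


def run_ablation(
    variant: AblationVariant | str,
    data: Dataset,
    cfg: PipelineConfig | None = None,
    seed: int = 0,
) -> dict[str, EvalReport]:
    """Run one ablation variant; reports on the held-out test set and on
    the entire dataset (which includes signals seen in training)."""
    test_report, all_report, _ = run_pipeline(variant, data, cfg, seed)
    return {"test": test_report, "all": all_report}
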