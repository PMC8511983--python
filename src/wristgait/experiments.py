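"""Canned end-to-end experiments on the synthetic study conditions.

These functions package the headline analyses so they can be reproduced with
one call: recovering the default class structure with every architecture
plus a feature baseline, and quantifying the generalization gap between a
segment-level split and a blind test on held-out subjects.
"""

from __future__ import annotations

import numpy as np

from .data import SplitSpec, build_segment_set, split
from .evaluation import evaluate, score
from .features import extract_features, fit_baseline, select_features
from .models import ARCHS, ModelSpec, SequenceClassifier, TrainConfig
from .synth import SimConfig, default_style_bank, simulate_dataset

__all__ = ["parameter_recovery", "holdout_comparison"]


def _dataset(seed, n_classes, n_subjects, duration_s, T):
    cfg = SimConfig(
        styles=default_style_bank(n_classes),
        n_subjects=n_subjects,
        duration_s=duration_s,
        seed=seed,
    )
    return build_segment_set(simulate_dataset(cfg), T=T)


def parameter_recovery(
    seed: int = 0,
    n_classes: int = 6,
    n_subjects: int = 8,
    duration_s: float = 60.0,
    T: int = 150,
    hidden_size: int = 64,
    archs: tuple = ARCHS,
    baselines: tuple = ("naive_bayes",),
    rnn_epochs: int = 35,
    conv_epochs: int = 60,
    test_fraction: float = 0.2,
) -> dict:
    """Held-out accuracy of every architecture and baseline on one split.

    Returns ``{name: {"accuracy": ..., "weighted_f1": ..., "n_test": ...}}``.
    Recurrent models run at ``hidden_size`` (not the h = T default) to keep
    desk-scale runtimes; the data conditions are the generator defaults.
    """
    dataset = _dataset(seed, n_classes, n_subjects, duration_s, T)
    train, test = split(
        dataset, SplitSpec("segment_random", test_fraction, seed=seed)
    )
    out: dict = {}
    for name in baselines:
        table = select_features(extract_features(train))
        model = fit_baseline(table, name, seed=seed)
        test_table = extract_features(test)
        rep = score(test_table.labels, model.predict(test_table), n_classes)
        out[name] = {"accuracy": rep.accuracy,
                     "weighted_f1": rep.weighted_f1, "n_test": len(test)}
    for arch in archs:
        spec = ModelSpec(arch=arch, T=T, D=dataset.D, n_classes=n_classes,
                         hidden_size=hidden_size, seed=seed)
        epochs = conv_epochs if arch == "conv1d" else rnn_epochs
        res = SequenceClassifier(spec).fit(
            train, test,
            TrainConfig(max_epochs=epochs, early_stop_patience=6, seed=seed),
        )
        rep = evaluate(res, test)
        out[arch] = {"accuracy": rep.accuracy,
                     "weighted_f1": rep.weighted_f1, "n_test": len(test)}
    return out


def holdout_comparison(
    seed: int = 0,
    n_classes: int = 6,
    n_subjects: int = 6,
    duration_s: float = 30.0,
    T: int = 100,
    arch: str = "conv1d",
    hidden_size: int = 32,
    max_epochs: int = 30,
    test_fraction: float = 0.25,
) -> dict:
    """Segment-random vs subject-holdout accuracy for the same model.

    The subject-holdout side emulates a blind test on people unseen during
    training; with per-subject cadence/amplitude variation it is expected to
    generalize no better than the segment-level split.
    """
    dataset = _dataset(seed, n_classes, n_subjects, duration_s, T)
    out = {}
    for mode in ("segment_random", "subject_holdout"):
        train, test = split(dataset, SplitSpec(mode, test_fraction, seed=seed))
        spec = ModelSpec(arch=arch, T=T, D=dataset.D, n_classes=n_classes,
                         hidden_size=hidden_size, seed=seed)
        res = SequenceClassifier(spec).fit(
            train, test,
            TrainConfig(max_epochs=max_epochs, early_stop_patience=6,
                        seed=seed),
        )
        out[mode] = evaluate(res, test).accuracy
    return out
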