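"""Classification metrics, confusion matrices, attention traces, embeddings.

The headline metric is the support-weighted F1 score

    Fm = sum_c (N_c / N_tot) * 2 P_c R_c / (P_c + R_c),

with per-class precision/recall read off an M x M confusion matrix whose
rows are true classes and columns predictions.  Classes never predicted or
never present get P (resp. R) = 0 by convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data import Segment, SegmentSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "AttentionTrace",
    "confusion_matrix",
    "score",
    "evaluate",
    "attention_trace",
    "render_attention",
    "export_embeddings",
]


@dataclass
class EvalReport:
    """Per-class and aggregate classification metrics."""

    per_class: list  # (class_id, precision, recall, f1, support)
    accuracy: float
    weighted_f1: float
    confusion: np.ndarray
    n_total: int

    def summary(self) -> str:
        lines = [
            f"{'class':>5} {'precision':>10} {'recall':>10} {'f1':>10} "
            f"{'support':>8}",
        ]
        for cid, p, r, f1, n in self.per_class:
            lines.append(f"{cid:>5} {p:>10.4f} {r:>10.4f} {f1:>10.4f} {n:>8}")
        lines.append("")
        lines.append(f"accuracy    {self.accuracy:.4f}   (n={self.n_total})")
        lines.append(f"weighted F1 {self.weighted_f1:.4f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.per_class,
            columns=["class_id", "precision", "recall", "f1", "support"],
        )
        df.to_csv(path, index=False)

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "weighted_f1": self.weighted_f1,
            "n_total": self.n_total,
            "confusion": self.confusion.tolist(),
            "per_class": [
                {"class_id": int(c), "precision": p, "recall": r,
                 "f1": f, "support": int(n)}
                for c, p, r, f, n in self.per_class
            ],
        }


@dataclass
class AttentionTrace:
    """One segment's attention weights paired with its raw channels."""

    alpha: np.ndarray  # (T,)
    channels: np.ndarray  # (T, D)
    predicted_class: int
    true_class: int
    recording_id: str = ""
    start_index: int = 0


def confusion_matrix(true, pred, n_classes: int) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    true = np.asarray(true, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if true.shape != pred.shape:
        raise ValueError("true and pred must have the same length")
    for name, v in (("true", true), ("pred", pred)):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError(f"{name} labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (true, pred), 1)
    return cm


def score(true, pred, n_classes: int) -> EvalReport:
    """Per-class P/R/F1, accuracy and weighted F1 from label vectors."""
    cm = confusion_matrix(true, pred, n_classes)
    n_tot = int(cm.sum())
    if n_tot == 0:
        raise ValueError("cannot score an empty prediction set")
    per_class = []
    weighted = 0.0
    for c in range(n_classes):
        tp = cm[c, c]
        support = int(cm[c].sum())
        pred_c = int(cm[:, c].sum())
        if pred_c == 0 and support > 0:
            warnings.warn(f"class {c} never predicted; precision set to 0",
                          stacklevel=2)
        p = tp / pred_c if pred_c else 0.0
        r = tp / support if support else 0.0
        f1 = 2.0 * p * r / (p + r) if (p + r) else 0.0
        per_class.append((c, p, r, f1, support))
        weighted += (support / n_tot) * f1
    return EvalReport(
        per_class=per_class,
        accuracy=float(np.trace(cm) / n_tot),
        weighted_f1=float(weighted),
        confusion=cm,
        n_total=n_tot,
    )


def evaluate(results, dataset: SegmentSet) -> EvalReport:
    """Run a fitted classifier over a segment set and score it."""
    if len(dataset.class_vocabulary) != results.spec.n_classes:
        raise ValueError("dataset vocabulary does not match the model")
    pred = results.predict(dataset)
    return score(dataset.labels(), pred, results.spec.n_classes)


def attention_trace(results, seg: Segment) -> AttentionTrace:
    """Attention weights of one segment, index-aligned to its samples."""
    if not results.spec.has_attention:
        raise ValueError(
            f"architecture {results.spec.arch!r} produces no attention trace"
        )
    probs, pred, alpha = results.classify(seg.data)
    return AttentionTrace(
        alpha=alpha,
        channels=np.asarray(seg.data),
        predicted_class=pred,
        true_class=seg.class_id,
        recording_id=seg.source_recording_id,
        start_index=seg.start_index,
    )


def render_attention(trace: AttentionTrace, path) -> None:
    """Plot the D channels above a darkness-coded strip of alpha.

    Sample t of every channel sits directly above strip cell t, so attention
    can be read against the raw signal.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    T, D = trace.channels.shape
    fig, axes = plt.subplots(
        D + 1, 1, figsize=(8, 1.2 * D + 1.2), sharex=True,
        gridspec_kw={"height_ratios": [1.0] * D + [0.5]},
    )
    t = np.arange(T)
    for d in range(D):
        axes[d].plot(t, trace.channels[:, d], lw=0.8)
        axes[d].set_ylabel(f"ch{d}", fontsize=7)
    axes[-1].imshow(
        trace.alpha[None, :], aspect="auto", cmap="Purples",
        extent=(-0.5, T - 0.5, 0, 1), vmin=0.0,
    )
    axes[-1].set_yticks([])
    axes[-1].set_xlabel("sample index")
    fig.suptitle(
        f"true={trace.true_class} pred={trace.predicted_class} "
        f"({trace.recording_id}@{trace.start_index})",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def export_embeddings(
    results, dataset: SegmentSet, path, tsne: bool = False, seed: int = 0
) -> None:
    """Write per-segment penultimate-layer embeddings to CSV.

    Columns: e0..e{E-1}, true label, predicted label, subject; with
    ``tsne=True`` two projection columns (fixed seed, perplexity 30) are
    appended for 2-D visualization.
    """
    import pandas as pd

    x = dataset.tensor()
    emb = results.embed(x)
    probs = results.predict_proba(dataset)
    df = pd.DataFrame(emb, columns=[f"e{i}" for i in range(emb.shape[1])])
    df["true_label"] = dataset.labels()
    df["pred_label"] = probs.argmax(axis=1)
    df["subject"] = dataset.subjects()
    if tsne:
        from sklearn.manifold import TSNE

        perp = min(30.0, max(2.0, (len(dataset) - 1) / 3.0))
        proj = TSNE(
            n_components=2, random_state=seed, perplexity=perp, init="pca"
        ).fit_transform(emb)
        df["tsne_x"] = proj[:, 0]
        df["tsne_y"] = proj[:, 1]
    df.to_csv(path, index=False)
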