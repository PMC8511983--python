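"""Deep sequence classifiers for fixed-length inertial windows.

Five architectures over a T x D window: a temporal ConvNet (``conv1d``),
two-layer stacked LSTM / GRU encoders (``lstm``, ``gru``), and their
multiplicative-attention variants (``lstm_att``, ``gru_att``).  The attention
head scores every encoder state against the last one with a bilinear form,

    score(a_T, a_t') = a_T Wa a_t'^T,        alpha = softmax(score),
    c_T = sum_t' alpha_t' a_t',              (context vector)
    h~_T = tanh(Wc [c_T ; a_T]),             (attentional hidden state)
    p(y | x) = softmax(Ws h~_T),

so alpha is a per-time-step relevance distribution that can be plotted
against the raw signal.  Non-attention architectures share the same 64-d
embedding head (``tanh`` of a dense projection) before the softmax.

Training minimizes mean categorical cross-entropy with Adam
(lr 1e-3, beta1 0.9, beta2 0.999 by default) with dropout on the embedding
and early stopping on validation loss.  Everything runs on the package's
numpy autodiff engine, so results are bit-deterministic under a fixed seed.

The public surface follows the Model/Results convention:

    >>> model = SequenceClassifier(ModelSpec(arch="lstm_att", T=150, D=6,
    ...                                      n_classes=6, hidden_size=64))
    >>> res = model.fit(train_set, val_set, TrainConfig(max_epochs=20))
    >>> res.predict(test_set), res.summary()
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import SegmentSet

ARCHS = ("conv1d", "lstm", "gru", "lstm_att", "gru_att")

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "SequenceClassifier",
    "ClassifierResults",
    "multiplicative_attention",
    "cross_entropy_loss",
    "attention_path",
]


@dataclass
class ModelSpec:
    """Architecture and hyperparameters of one classifier."""

    arch: str
    T: int
    D: int
    n_classes: int
    hidden_size: int | None = None  # defaults to T (recurrent archs)
    embed_size: int = 64
    dropout_rate: float = 0.2
    conv_channels: tuple = (64, 64, 64)
    kernel_size: int = 3
    stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHS:
            raise ValueError(f"arch must be one of {ARCHS}")
        if self.hidden_size is None:
            self.hidden_size = self.T
        if self.hidden_size <= 0 or self.embed_size <= 0:
            raise ValueError("hidden_size and embed_size must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.arch == "conv1d" and self.T < 2 ** len(self.conv_channels):
            raise ValueError(
                "T too short for the conv1d pooling pyramid "
                f"(need >= {2 ** len(self.conv_channels)})"
            )

    @property
    def has_attention(self) -> bool:
        return self.arch.endswith("_att")


@dataclass
class TrainConfig:
    """Optimizer and schedule settings (Adam with early stopping)."""

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    max_epochs: int = 100
    early_stop_patience: int = 10
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# -- plain-numpy reference forms -------------------------------------------


def multiplicative_attention(states, Wa, Wc=None, bc=None):
    """Bilinear attention over a (T, h) or (B, T, h) state sequence.

    Returns ``(alpha, context, h_tilde)``; ``h_tilde`` is None unless the
    combination weights ``Wc`` (and bias ``bc``) are supplied.  The last
    state serves as the query.
    """
    a = np.asarray(states, dtype=float)
    squeeze = a.ndim == 2
    if squeeze:
        a = a[None]
    aT = a[:, -1, :]
    scores = np.einsum("bh,hk,btk->bt", aT, np.asarray(Wa, dtype=float), a)
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    alpha = e / e.sum(axis=1, keepdims=True)
    context = np.einsum("bt,bth->bh", alpha, a)
    h_tilde = None
    if Wc is not None:
        cat = np.concatenate([context, aT], axis=1)
        h_tilde = np.tanh(cat @ np.asarray(Wc, dtype=float)
                          + (0.0 if bc is None else np.asarray(bc)))
    if squeeze:
        alpha, context = alpha[0], context[0]
        h_tilde = None if h_tilde is None else h_tilde[0]
    return alpha, context, h_tilde


def cross_entropy_loss(y_true, y_prob) -> float:
    """Mean categorical cross-entropy of one-hot targets vs probabilities."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_prob = np.clip(np.atleast_2d(np.asarray(y_prob, dtype=float)), 1e-12, 1.0)
    if y_true.shape != y_prob.shape:
        raise ValueError("shape mismatch between targets and probabilities")
    return float(-(y_true * np.log(y_prob)).sum(axis=1).mean())


# -- shared attention head (single code path for forward, tests, plots) -----


def _attention_head(S, aT, p, dropout_rate=0.0, training=False, rng=None):
    """Graph ops of the attention + classification head.

    S: (B, T, h) tensor of encoder states; aT: (B, h) last state.
    Returns (alpha, context, h_tilde, logits) as graph tensors.
    """
    u = aT @ p["Wa"]
    alpha = ad.softmax_rows(ad.bdot(u, S))
    context = ad.wsum(alpha, S)
    h_tilde = ad.tanh(ad.concat_cols(context, aT) @ p["Wc"] + p["bc"])
    dropped = ad.dropout(h_tilde, dropout_rate, rng, training)
    logits = dropped @ p["Ws"] + p["bs"]
    return alpha, context, h_tilde, logits


def attention_path(states, params, y_onehot):
    """Differentiable attention + cross-entropy path from leaf tensors.

    ``states`` is a (B, T, h) array; ``params`` maps Wa/Wc/bc/Ws/bs to
    arrays.  Returns ``(loss, leaves)`` where ``leaves`` maps every input
    (including ``"states"``) to its leaf Tensor, for gradient checking the
    exact code path the classifier uses.
    """
    S = ad.parameter(np.asarray(states, dtype=float))
    p = {k: ad.parameter(np.asarray(v, dtype=float)) for k, v in params.items()}
    aT = ad.slice_time(S, S.shape[1] - 1)
    _, _, _, logits = _attention_head(S, aT, p)
    loss, _ = ad.softmax_cross_entropy(logits, np.asarray(y_onehot, dtype=float))
    leaves = dict(p)
    leaves["states"] = S
    return loss, leaves


# -- the model --------------------------------------------------------------


class SequenceClassifier:
    """A deep walking-style classifier specified by a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.params = self._init_params(spec)

    # parameter initialization: Glorot-uniform weights, zero biases,
    # LSTM forget-gate bias 1 for stable early training.
    @staticmethod
    def _init_params(spec: ModelSpec) -> dict:
        rng = np.random.default_rng(spec.seed)
        dt = np.float32
        p: dict[str, np.ndarray] = {}

        def glorot(n_in, n_out):
            lim = np.sqrt(6.0 / (n_in + n_out))
            return rng.uniform(-lim, lim, size=(n_in, n_out)).astype(dt)

        h, D, E, M = spec.hidden_size, spec.D, spec.embed_size, spec.n_classes
        if spec.arch == "conv1d":
            cin = D
            for i, cout in enumerate(spec.conv_channels):
                p[f"convW{i}"] = glorot(spec.kernel_size * cin, cout)
                p[f"convb{i}"] = np.zeros(cout, dtype=dt)
                cin = cout
            p["We"] = glorot(cin, E)
            p["be"] = np.zeros(E, dtype=dt)
        elif spec.arch.startswith("lstm"):
            for layer, n_in in enumerate((D, h)):
                p[f"W{layer}"] = glorot(n_in + h, 4 * h)
                b = np.zeros(4 * h, dtype=dt)
                b[h : 2 * h] = 1.0  # forget-gate bias
                p[f"b{layer}"] = b
        else:  # gru
            for layer, n_in in enumerate((D, h)):
                p[f"Wzr{layer}"] = glorot(n_in + h, 2 * h)
                p[f"bzr{layer}"] = np.zeros(2 * h, dtype=dt)
                p[f"Wn{layer}"] = glorot(n_in + h, h)
                p[f"bn{layer}"] = np.zeros(h, dtype=dt)
        if spec.arch != "conv1d":
            if spec.has_attention:
                p["Wa"] = glorot(h, h)
                p["Wc"] = glorot(2 * h, E)
                p["bc"] = np.zeros(E, dtype=dt)
            else:
                p["We"] = glorot(h, E)
                p["be"] = np.zeros(E, dtype=dt)
        p["Ws"] = glorot(E, M)
        p["bs"] = np.zeros(M, dtype=dt)
        return p

    # -- forward graphs -----------------------------------------------------

    def _recurrent_states(self, x, p):
        """Run the 2-layer stacked LSTM/GRU; returns list of layer-2 states."""
        B, T, _ = x.shape
        h = self.spec.hidden_size
        dt = x.dtype
        is_lstm = self.spec.arch.startswith("lstm")
        states: list[Tensor] = []
        hs = [Tensor(np.zeros((B, h), dtype=dt)) for _ in range(2)]
        cs = [Tensor(np.zeros((B, h), dtype=dt)) for _ in range(2)]
        for t in range(T):
            inp = Tensor(np.ascontiguousarray(x[:, t, :]))
            for layer in range(2):
                if is_lstm:
                    z = (ad.concat_cols(inp, hs[layer]) @ p[f"W{layer}"]
                         + p[f"b{layer}"])
                    i = ad.sigmoid(ad.slice_cols(z, 0, h))
                    f = ad.sigmoid(ad.slice_cols(z, h, 2 * h))
                    g = ad.tanh(ad.slice_cols(z, 2 * h, 3 * h))
                    o = ad.sigmoid(ad.slice_cols(z, 3 * h, 4 * h))
                    cs[layer] = f * cs[layer] + i * g
                    hs[layer] = o * ad.tanh(cs[layer])
                else:
                    # GRU (reset applied to the state entering the candidate)
                    zr = ad.sigmoid(
                        ad.concat_cols(inp, hs[layer]) @ p[f"Wzr{layer}"]
                        + p[f"bzr{layer}"]
                    )
                    zg = ad.slice_cols(zr, 0, h)
                    rg = ad.slice_cols(zr, h, 2 * h)
                    n = ad.tanh(
                        ad.concat_cols(inp, rg * hs[layer]) @ p[f"Wn{layer}"]
                        + p[f"bn{layer}"]
                    )
                    one_minus_z = zg * -1.0 + 1.0
                    hs[layer] = zg * hs[layer] + one_minus_z * n
                inp = hs[layer]
            states.append(hs[1])
        return states

    def _forward(self, x, params_t, training=False, rng=None):
        """Build the graph for a batch; returns dict of output tensors."""
        spec = self.spec
        p = params_t
        if spec.arch == "conv1d":
            xt = Tensor(x)
            cur = xt
            for i in range(len(spec.conv_channels)):
                cur = ad.relu(
                    ad.conv1d_same(cur, p[f"convW{i}"], p[f"convb{i}"],
                                   spec.kernel_size)
                )
                cur = ad.maxpool1d(cur, 2)
            pooled = ad.mean_over_time(cur)
            embed = ad.tanh(pooled @ p["We"] + p["be"])
            dropped = ad.dropout(embed, spec.dropout_rate, rng, training)
            logits = dropped @ p["Ws"] + p["bs"]
            return {"logits": logits, "embed": embed, "alpha": None,
                    "states": cur}
        states = self._recurrent_states(x, p)
        aT = states[-1]
        if spec.has_attention:
            S = ad.stack_time(states)
            alpha, context, h_tilde, logits = _attention_head(
                S, aT, p, spec.dropout_rate, training, rng
            )
            return {"logits": logits, "embed": h_tilde, "alpha": alpha,
                    "states": states}
        embed = ad.tanh(aT @ p["We"] + p["be"])
        dropped = ad.dropout(embed, spec.dropout_rate, rng, training)
        logits = dropped @ p["Ws"] + p["bs"]
        return {"logits": logits, "embed": embed, "alpha": None,
                "states": states}

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        train_set: SegmentSet,
        val_set: SegmentSet | None = None,
        config: TrainConfig | None = None,
        verbose: bool = False,
    ) -> "ClassifierResults":
        config = config or TrainConfig()
        spec = self.spec
        x_tr = train_set.tensor().astype(np.float32)
        y_tr = train_set.labels()
        if x_tr.shape[1] != spec.T or x_tr.shape[2] != spec.D:
            raise ValueError("training set shape does not match ModelSpec")
        onehot_tr = np.eye(spec.n_classes, dtype=np.float32)[y_tr]
        if val_set is not None and len(val_set):
            x_va = val_set.tensor().astype(np.float32)
            y_va = val_set.labels()
        else:
            x_va = y_va = None

        rng = np.random.default_rng(config.seed)
        params_t = {k: ad.parameter(v) for k, v in self.params.items()}
        opt = _Adam(params_t, config)
        history: list[dict] = []
        best_val = np.inf
        best_params = None
        patience_left = config.early_stop_patience
        n = x_tr.shape[0]

        for epoch in range(config.max_epochs):
            order = rng.permutation(n)
            tot_loss = tot_correct = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                out = self._forward(x_tr[idx], params_t, training=True, rng=rng)
                loss, probs = ad.softmax_cross_entropy(
                    out["logits"], onehot_tr[idx]
                )
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        "non-finite training loss; lower the learning rate or "
                        "tighten grad_clip"
                    )
                for t in params_t.values():
                    t.grad = None
                loss.backward()
                opt.step()
                tot_loss += float(loss.data) * len(idx)
                tot_correct += (probs.argmax(axis=1) == y_tr[idx]).sum()
            row = {
                "epoch": epoch,
                "train_loss": tot_loss / n,
                "train_acc": tot_correct / n,
            }
            if x_va is not None:
                va_probs = self._predict_proba_arr(x_va, params_t)
                row["val_loss"] = cross_entropy_loss(
                    np.eye(spec.n_classes)[y_va], va_probs
                )
                row["val_acc"] = float(
                    (va_probs.argmax(axis=1) == y_va).mean()
                )
                if row["val_loss"] < best_val - 1e-6:
                    best_val = row["val_loss"]
                    best_params = {k: t.data.copy() for k, t in params_t.items()}
                    patience_left = config.early_stop_patience
                else:
                    patience_left -= 1
            history.append(row)
            if verbose:
                print("  ".join(f"{k}={v:.4f}" if k != "epoch" else f"epoch={v}"
                                for k, v in row.items()))
            if x_va is not None and patience_left <= 0:
                break
        final = best_params or {k: t.data.copy() for k, t in params_t.items()}
        self.params = final
        return ClassifierResults(
            spec=spec,
            params=final,
            history=history,
            class_vocabulary=list(train_set.class_vocabulary),
            train_config=config,
        )

    def _predict_proba_arr(self, x, params_t, batch=256):
        probs = []
        for start in range(0, x.shape[0], batch):
            out = self._forward(x[start : start + batch], params_t)
            z = out["logits"].data
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(probs, axis=0)


class _Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: dict, config: TrainConfig):
        self.params = params
        self.cfg = config
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.t = 0

    def step(self):
        cfg = self.cfg
        grads = {
            k: (t.grad if t.grad is not None else np.zeros_like(t.data))
            for k, t in self.params.items()
        }
        if cfg.grad_clip:
            norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
            if norm > cfg.grad_clip:
                scale = cfg.grad_clip / norm
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = cfg.beta1, cfg.beta2
        for k, t in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            t.data -= (cfg.learning_rate * mhat /
                       (np.sqrt(vhat) + 1e-8)).astype(t.data.dtype)


@dataclass
class ClassifierResults:
    """A fitted classifier: learned parameters, history, inference methods."""

    spec: ModelSpec
    params: dict
    history: list
    class_vocabulary: list
    train_config: TrainConfig | None = None

    def _model(self) -> SequenceClassifier:
        m = SequenceClassifier.__new__(SequenceClassifier)
        m.spec = self.spec
        m.params = self.params
        return m

    def _tensors(self):
        return {k: Tensor(v) for k, v in self.params.items()}

    def _forward_batch(self, x):
        return self._model()._forward(
            np.asarray(x, dtype=np.float32), self._tensors()
        )

    # -- inference ----------------------------------------------------------

    def classify(self, x):
        """Probabilities, argmax label and (for *_att) attention weights.

        ``x`` is one T x D window or a batch (n, T, D).
        """
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != (self.spec.T, self.spec.D):
            raise ValueError("input shape does not match ModelSpec")
        out = self._forward_batch(x)
        z = out["logits"].data
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        pred = probs.argmax(axis=1)  # argmax -> lowest index on ties
        alpha = out["alpha"].data if out["alpha"] is not None else None
        if single:
            return probs[0], int(pred[0]), None if alpha is None else alpha[0]
        return probs, pred, alpha

    def predict_proba(self, dataset: SegmentSet, batch=256) -> np.ndarray:
        x = dataset.tensor().astype(np.float32)
        return self._model()._predict_proba_arr(x, self._tensors(), batch)

    def predict(self, dataset: SegmentSet) -> np.ndarray:
        return self.predict_proba(dataset).argmax(axis=1)

    def encode(self, x):
        """Encoder output: hidden-state sequence (T, h) per input window."""
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 2
        if single:
            x = x[None]
        out = self._forward_batch(x)
        states = out["states"]
        if isinstance(states, list):
            arr = np.stack([s.data for s in states], axis=1)
        else:  # conv1d temporal feature map
            arr = states.data
        return arr[0] if single else arr

    def embed(self, x) -> np.ndarray:
        """The 64-d penultimate activation used for 2-D visualization."""
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 2
        if single:
            x = x[None]
        e = self._forward_batch(x)["embed"].data
        return e[0] if single else e

    def attention_weights(self, x) -> np.ndarray:
        if not self.spec.has_attention:
            raise ValueError(
                f"architecture {self.spec.arch!r} has no attention weights"
            )
        _, _, alpha = self.classify(x)
        return alpha

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        n_par = sum(int(np.prod(v.shape)) for v in self.params.values())
        lines = [
            "Sequence classifier results",
            "=" * 42,
            f"architecture:     {self.spec.arch}",
            f"window (T x D):   {self.spec.T} x {self.spec.D}",
            f"classes:          {self.spec.n_classes}",
            f"hidden size:      {self.spec.hidden_size}",
            f"embedding size:   {self.spec.embed_size}",
            f"parameters:       {n_par}",
            f"epochs trained:   {len(self.history)}",
        ]
        if self.history:
            last = self.history[-1]
            lines.append(f"final train loss: {last['train_loss']:.4f} "
                         f"(acc {last['train_acc']:.4f})")
            if "val_loss" in last:
                best = min(h["val_loss"] for h in self.history)
                lines.append(f"best val loss:    {best:.4f}")
                lines.append(f"final val acc:    {last['val_acc']:.4f}")
        return "\n".join(lines)

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "format_version": 1,
            "spec": asdict(self.spec),
            "vocabulary": self.class_vocabulary,
            "history": self.history,
        }
        np.savez(path, __meta__=json.dumps(meta),
                 **{f"param_{k}": v for k, v in self.params.items()})

    @classmethod
    def load(cls, path) -> "ClassifierResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            if meta["format_version"] != 1:
                raise ValueError("unsupported checkpoint version")
            spec_d = meta["spec"]
            spec_d["conv_channels"] = tuple(spec_d["conv_channels"])
            spec = ModelSpec(**spec_d)
            params = {
                k[len("param_"):]: z[k] for k in z.files if k.startswith("param_")
            }
        expected = SequenceClassifier._init_params(spec)
        for k, v in expected.items():
            if k not in params or params[k].shape != v.shape:
                raise ValueError(f"checkpoint parameter {k!r} missing or "
                                 "shape-incompatible with its spec")
        return cls(spec=spec, params=params, history=meta["history"],
                   class_vocabulary=meta["vocabulary"])
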