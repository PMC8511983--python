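"""Per-channel timeseries feature bank, FDR-controlled selection, baselines.

The feature-based branch of the pipeline turns every standardized T x D
segment into a vector of scalar descriptors (one bank applied to each of the
D channels), ranks features by a one-vs-rest Kolmogorov--Smirnov relevance
test, keeps those surviving a Benjamini--Yekutieli false-discovery-rate
step-up (valid under arbitrary dependence, harmonic correction
``c(m) = sum_{i<=m} 1/i``), truncates to the ``top_k`` most significant, and
fits classical classifiers (naive Bayes, random forest, RBF-kernel SVM) on
the surviving columns.

Feature families (entropy in natural log throughout; undefined values, e.g.
the autocorrelation of a constant series, return NaN and are median-imputed
per column downstream):

==========================  ==================================================
sum_values                  sum of the series
fft_coefficient             real/imag/abs of DFT coefficient ``k`` (rfft)
autocorrelation             lag-``lag`` autocorrelation coefficient
partial_autocorrelation     PACF value at ``lag`` (Levinson--Durbin)
ar_coefficient              coefficient ``k`` of an AR(``order``) fit
fourier_entropy             binned entropy of the Welch power spectrum
change_quantiles            mean |diff| inside a quantile corridor
binned_entropy              entropy of an equal-width value histogram
agg_linear_trend            OLS slope/intercept/rvalue over chunk aggregates
permutation_entropy         entropy of ordinal patterns of order ``order``
number_peaks                peaks with support ``n`` on both sides
lempel_ziv_complexity       LZ76 phrase count / length, median-binarized
==========================  ==================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .data import SegmentSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "FeatureTable",
    "compute_feature",
    "default_registry",
    "extract_features",
    "significance_test",
    "benjamini_yekutieli_select",
    "fit_baseline",
    "BaselineModel",
]


@dataclass(frozen=True)
class FeatureSpec:
    """A feature family name plus its parameter binding."""

    name: str
    parameters: tuple = ()  # sorted (key, value) pairs, hashable

    @classmethod
    def of(cls, name: str, **params) -> "FeatureSpec":
        return cls(name, tuple(sorted(params.items())))

    @property
    def params(self) -> dict:
        return dict(self.parameters)

    def label(self) -> str:
        ps = "_".join(f"{k}-{v}" for k, v in self.parameters)
        return f"{self.name}__{ps}" if ps else self.name


# -- individual families ----------------------------------------------------


def _sum_values(x, p):
    return float(np.sum(x))


def _fft_coefficient(x, p):
    k = p["k"]
    attr = p.get("attr", "abs")
    coeffs = np.fft.rfft(x)
    if k >= len(coeffs):
        return np.nan
    c = coeffs[k]
    return float({"real": c.real, "imag": c.imag, "abs": abs(c)}[attr])


def _autocorrelation(x, p):
    lag = p["lag"]
    n = len(x)
    if lag >= n:
        return np.nan
    v = np.var(x)
    if v < 1e-12:
        return np.nan
    m = np.mean(x)
    return float(np.sum((x[: n - lag] - m) * (x[lag:] - m)) / ((n - lag) * v))


from functools import lru_cache


@lru_cache(maxsize=2048)
def _pacf_cached(buf: bytes, n: int, nlags: int):
    from statsmodels.tsa.stattools import pacf

    x = np.frombuffer(buf, dtype=float)
    try:
        return pacf(x, nlags=nlags, method="ld")
    except Exception:
        return np.full(nlags + 1, np.nan)


def _partial_autocorrelation(x, p):
    lag = p["lag"]
    if lag == 0:
        return 1.0
    if np.var(x) < 1e-12 or len(x) <= 2 * lag:
        return np.nan
    # cache across the parameter grid: one Levinson-Durbin fit per series
    vals = _pacf_cached(np.ascontiguousarray(x, dtype=float).tobytes(),
                        len(x), max(lag, 10))
    return float(vals[lag]) if lag < len(vals) else np.nan


@lru_cache(maxsize=2048)
def _ar_params_cached(buf: bytes, order: int):
    from statsmodels.tsa.ar_model import AutoReg

    x = np.frombuffer(buf, dtype=float)
    try:
        return AutoReg(x, lags=order).fit().params
    except Exception:
        return np.full(order + 1, np.nan)


def _ar_coefficient(x, p):
    order, k = p["order"], p["k"]
    if np.var(x) < 1e-12 or len(x) <= order + 1:
        return np.nan
    params = _ar_params_cached(
        np.ascontiguousarray(x, dtype=float).tobytes(), order
    )
    # params[0] is the intercept, params[1:] the lag coefficients
    return float(params[k + 1]) if k + 1 < len(params) else np.nan


def _binned_entropy_of(values, n_bins):
    hist, _ = np.histogram(values, bins=n_bins)
    probs = hist[hist > 0] / len(values)
    return float(-(probs * np.log(probs)).sum())


def _fourier_entropy(x, p):
    if np.var(x) < 1e-12:
        return np.nan
    _, pxx = sp_signal.welch(x, nperseg=min(len(x), 256))
    return _binned_entropy_of(pxx / pxx.max(), p["bins"])


def _change_quantiles(x, p):
    ql, qh = p["ql"], p["qh"]
    lo, hi = np.quantile(x, ql), np.quantile(x, qh)
    if lo == hi:
        return 0.0
    inside = (x >= lo) & (x <= hi)
    ok = inside[:-1] & inside[1:]
    if not ok.any():
        return 0.0
    d = np.diff(x)[ok]
    if p.get("isabs", True):
        d = np.abs(d)
    return float(np.mean(d))


def _binned_entropy(x, p):
    return _binned_entropy_of(x, p["max_bins"])


def _agg_linear_trend(x, p):
    size, attr = p["chunk_len"], p["attr"]
    aggfun = {"mean": np.mean, "min": np.min, "max": np.max}[p.get("agg", "mean")]
    n_chunks = len(x) // size
    if n_chunks < 2:
        return np.nan
    agg = [aggfun(x[i * size : (i + 1) * size]) for i in range(n_chunks)]
    res = sp_stats.linregress(np.arange(n_chunks), agg)
    return float(getattr(res, attr))


def _permutation_entropy(x, p):
    order = p["order"]
    tau = p.get("tau", 1)
    n = len(x) - (order - 1) * tau
    if n < 1:
        return np.nan
    emb = np.stack([x[i * tau : i * tau + n] for i in range(order)], axis=1)
    patterns = np.apply_along_axis(
        lambda r: hash(tuple(np.argsort(r, kind="stable"))), 1, emb
    )
    _, counts = np.unique(patterns, return_counts=True)
    probs = counts / n
    return float(-(probs * np.log(probs)).sum())


def _number_peaks(x, p):
    n = p["n"]
    T = len(x)
    count = 0
    for i in range(n, T - n):
        if all(x[i] > x[i - j] and x[i] > x[i + j] for j in range(1, n + 1)):
            count += 1
    return float(count)


def lz76_complexity(symbols) -> int:
    """LZ76 phrase count of a symbol sequence (sub-string parse).

    Scans left to right, extending the current phrase while it has appeared
    as a contiguous substring before; each novel phrase increments the count.
    """
    s = list(symbols)
    n = len(s)
    phrases = 0
    ind, inc = 0, 1
    while ind + inc <= n:
        piece = s[ind : ind + inc]
        # has `piece` occurred earlier (any position strictly before ind+inc-1)?
        prefix = s[: ind + inc - 1]
        found = any(
            prefix[j : j + inc] == piece for j in range(len(prefix) - inc + 1)
        )
        if found:
            inc += 1
        else:
            phrases += 1
            ind += inc
            inc = 1
    if inc > 1:
        phrases += 1  # unterminated final phrase
    return phrases


def _lempel_ziv_complexity(x, p):
    med = np.median(x)
    bits = (np.asarray(x) > med).astype(int)
    return lz76_complexity(bits.tolist()) / len(bits)


_FAMILIES = {
    "sum_values": _sum_values,
    "fft_coefficient": _fft_coefficient,
    "autocorrelation": _autocorrelation,
    "partial_autocorrelation": _partial_autocorrelation,
    "ar_coefficient": _ar_coefficient,
    "fourier_entropy": _fourier_entropy,
    "change_quantiles": _change_quantiles,
    "binned_entropy": _binned_entropy,
    "agg_linear_trend": _agg_linear_trend,
    "permutation_entropy": _permutation_entropy,
    "number_peaks": _number_peaks,
    "lempel_ziv_complexity": _lempel_ziv_complexity,
}

_MIN_LENGTH = {
    "permutation_entropy": lambda p: (p["order"] - 1) * p.get("tau", 1) + 1,
    "autocorrelation": lambda p: p["lag"] + 1,
    "ar_coefficient": lambda p: p["order"] + 2,
}


def compute_feature(x, spec: FeatureSpec) -> float:
    """Evaluate one feature on a 1-d series; NaN marks an undefined value."""
    if spec.name not in _FAMILIES:
        raise ValueError(f"unknown feature family {spec.name!r}")
    x = np.asarray(x, dtype=float)
    p = spec.params
    need = _MIN_LENGTH.get(spec.name)
    if need is not None and len(x) < need(p):
        raise ValueError(f"series too short for {spec.label()}")
    return _FAMILIES[spec.name](x, p)


def default_registry() -> list[FeatureSpec]:
    """The default per-channel bank (~36 features per axis)."""
    S = FeatureSpec.of
    reg = [S("sum_values")]
    reg += [S("fft_coefficient", k=k, attr="abs") for k in range(4)]
    reg += [S("fft_coefficient", k=k, attr=a) for k in (1, 2) for a in ("real", "imag")]
    reg += [S("autocorrelation", lag=lag) for lag in (1, 2, 5, 10)]
    reg += [S("partial_autocorrelation", lag=lag) for lag in (1, 2, 5)]
    reg += [S("ar_coefficient", order=4, k=k) for k in range(3)]
    reg += [S("fourier_entropy", bins=b) for b in (5, 10)]
    reg += [
        S("change_quantiles", ql=ql, qh=qh, isabs=True)
        for ql, qh in ((0.0, 0.5), (0.5, 1.0), (0.25, 0.75))
    ]
    reg += [S("binned_entropy", max_bins=b) for b in (5, 10)]
    reg += [S("agg_linear_trend", chunk_len=10, attr=a) for a in ("slope", "intercept", "rvalue")]
    reg += [S("agg_linear_trend", chunk_len=5, attr="slope")]
    reg += [S("permutation_entropy", order=o) for o in (3, 5)]
    reg += [S("number_peaks", n=n) for n in (1, 3, 5)]
    reg += [S("lempel_ziv_complexity")]
    return reg


@dataclass
class FeatureTable:
    """n_segments x p feature matrix with names, labels and selection state."""

    matrix: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    p_values: np.ndarray | None = None
    selected: np.ndarray | None = None

    def selected_matrix(self) -> np.ndarray:
        if self.selected is None:
            raise ValueError("no selection mask set; run selection first")
        return self.matrix[:, self.selected]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    def selection_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "feature": self.feature_names,
                "p_value": self.p_values,
                "selected": self.selected,
            }
        ).to_csv(path, index=False)


def extract_features(
    dataset: SegmentSet, registry: list[FeatureSpec] | None = None
) -> FeatureTable:
    """Apply the bank per channel to every segment; median-impute NaNs."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if registry is None:
        registry = default_registry()
    if not registry:
        raise ValueError("empty feature registry")
    D = dataset.D
    names = [
        f"ch{c}.{spec.label()}" for c in range(D) for spec in registry
    ]
    mat = np.empty((len(dataset), D * len(registry)))
    for i, seg in enumerate(dataset):
        col = 0
        for c in range(D):
            x = seg.data[:, c]
            for spec in registry:
                mat[i, col] = compute_feature(x, spec)
                col += 1
    # per-column median imputation of undefined values
    for j in range(mat.shape[1]):
        bad = ~np.isfinite(mat[:, j])
        if bad.all():
            logger.warning("feature column %s is all-undefined; imputed to 0",
                           names[j])
            mat[:, j] = 0.0
        elif bad.any():
            mat[bad, j] = np.median(mat[~bad, j])
    return FeatureTable(mat, names, dataset.labels())


# -- significance testing and BY selection ----------------------------------


def significance_test(column, labels) -> float:
    """Multiclass relevance p-value for one feature column.

    Minimum over one-vs-rest two-sample Kolmogorov--Smirnov tests,
    Bonferroni-adjusted by the number of classes, clipped to [0, 1].
    """
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("significance test needs at least 2 classes")
    p_min = 1.0
    for c in classes:
        a = column[labels == c]
        b = column[labels != c]
        p = sp_stats.ks_2samp(a, b, method="auto").pvalue
        p_min = min(p_min, p)
    return float(np.clip(p_min * classes.size, 0.0, 1.0))


def benjamini_yekutieli_select(
    p_values, fdr_q: float = 0.05, top_k: int | None = 180
) -> np.ndarray:
    """BY step-up selection mask, truncated to the ``top_k`` smallest.

    Accepts the ``i`` smallest p-values where ``i`` is the largest index with
    ``p_(i) <= i * q / (m * c(m))`` and ``c(m)`` the harmonic sum; ties beyond
    ``top_k`` break by column order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < fdr_q < 1.0:
        raise ValueError("fdr_q must lie in (0, 1)")
    m = p.size
    mask = np.zeros(m, dtype=bool)
    if m == 0:
        return mask
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, m + 1) * fdr_q / (m * c_m)
    passing = np.flatnonzero(p[order] <= thresholds)
    if passing.size == 0:
        return mask
    k_star = passing[-1] + 1  # accept the k_star smallest
    accepted = order[:k_star]
    if top_k is not None and accepted.size > top_k:
        accepted = accepted[:top_k]  # argsort is stable: column-order ties
    mask[accepted] = True
    return mask


def select_features(
    table: FeatureTable, fdr_q: float = 0.05, top_k: int | None = 180
) -> FeatureTable:
    """Attach p-values and a BY selection mask to a feature table."""
    pvals = np.array(
        [significance_test(table.matrix[:, j], table.labels)
         for j in range(table.matrix.shape[1])]
    )
    table.p_values = pvals
    table.selected = benjamini_yekutieli_select(pvals, fdr_q, top_k)
    if not table.selected.any():
        logger.warning("BY selection kept no features at q=%g", fdr_q)
    return table


# -- classical baselines ----------------------------------------------------


@dataclass
class BaselineModel:
    """A fitted classical classifier over selected, re-standardized features."""

    kind: str
    pipeline: object
    selected: np.ndarray

    def predict(self, table: FeatureTable) -> np.ndarray:
        return self.pipeline.predict(table.matrix[:, self.selected])


def fit_baseline(table: FeatureTable, model: str, seed: int = 0) -> BaselineModel:
    """Fit naive Bayes / random forest / RBF-SVM on the selected columns."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import GaussianNB
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if table.selected is None or not table.selected.any():
        raise ValueError("no selected features; run select_features first")
    if np.unique(table.labels).size < 2:
        raise ValueError("need at least 2 classes")
    clf = {
        "naive_bayes": lambda: GaussianNB(),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "svm_rbf": lambda: SVC(kernel="rbf", random_state=seed),
    }
    if model not in clf:
        raise ValueError(f"unknown baseline {model!r}")
    pipe = make_pipeline(StandardScaler(), clf[model]())
    pipe.fit(table.selected_matrix(), table.labels)
    return BaselineModel(kind=model, pipeline=pipe, selected=table.selected)
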