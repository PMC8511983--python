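"""Recording/segment data model, sensor-log I/O, standardization, windowing.

A :class:`Recording` is one continuous 6-channel inertial stream (triaxial
accelerometer then triaxial gyroscope, 50 Hz by default) for one subject and
one walking-style class.  Learning operates on fixed-length standardized
windows (:class:`Segment`), cut without phase alignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical sensor-log column order (accelerometer in m/s^2, gyro in rad/s).
CHANNEL_NAMES = ("accel_x", "accel_y", "accel_z", "gyro_x", "gyro_y", "gyro_z")
N_CHANNELS = 6

class SensorLogFormatError(ValueError):
    """Raised when a sensor-log CSV violates the column contract."""


@dataclass
class Recording:
    """One labeled continuous 6-channel stream for one subject and class."""

    recording_id: str
    subject_id: int
    class_id: int
    sample_rate_hz: float
    channels: np.ndarray  # (N, 6), canonical column order
    timestamps: np.ndarray | None = None  # seconds, strictly increasing

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != N_CHANNELS:
            raise ValueError(
                f"channels must be (N, {N_CHANNELS}); got {self.channels.shape}"
            )
        if self.channels.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.isfinite(self.channels).all():
            raise ValueError("recording contains non-finite values")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if np.any(np.diff(self.timestamps) <= 0):
                raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]


@dataclass
class Segment:
    """A T x D standardized window, the unit of classification."""

    data: np.ndarray  # (T, D)
    class_id: int
    subject_id: int
    source_recording_id: str
    start_index: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if not np.isfinite(self.data).all():
            raise ValueError("segment contains non-finite values")


@dataclass
class SegmentSet:
    """An ordered collection of equally shaped segments."""

    segments: list[Segment]
    class_vocabulary: list[str]

    def __post_init__(self):
        if self.segments:
            T, D = self.segments[0].data.shape
            for s in self.segments:
                if s.data.shape != (T, D):
                    raise ValueError("all segments must share T and D")

    def __len__(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def T(self) -> int:
        return self.segments[0].data.shape[0]

    @property
    def D(self) -> int:
        return self.segments[0].data.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_vocabulary)

    def tensor(self) -> np.ndarray:
        """Stack into (n, T, D)."""
        return np.stack([s.data for s in self.segments])

    def labels(self) -> np.ndarray:
        return np.array([s.class_id for s in self.segments], dtype=int)

    def subjects(self) -> np.ndarray:
        return np.array([s.subject_id for s in self.segments], dtype=int)

    def subset(self, indices) -> "SegmentSet":
        return SegmentSet(
            [self.segments[i] for i in indices], list(self.class_vocabulary)
        )

    # -- versioned binary container (runtime artifact) ---------------------

    def save(self, path) -> None:
        np.savez(
            path,
            format_version=1,
            x=self.tensor(),
            y=self.labels(),
            subject=self.subjects(),
            start=np.array([s.start_index for s in self.segments]),
            recording=np.array(
                [s.source_recording_id for s in self.segments], dtype=object
            ),
            vocabulary=np.array(self.class_vocabulary, dtype=object),
        )

    @classmethod
    def load(cls, path) -> "SegmentSet":
        with np.load(path, allow_pickle=True) as z:
            if int(z["format_version"]) != 1:
                raise ValueError("unsupported SegmentSet container version")
            segs = [
                Segment(
                    data=z["x"][i],
                    class_id=int(z["y"][i]),
                    subject_id=int(z["subject"][i]),
                    source_recording_id=str(z["recording"][i]),
                    start_index=int(z["start"][i]),
                )
                for i in range(z["x"].shape[0])
            ]
            return cls(segs, [str(v) for v in z["vocabulary"]])


@dataclass
class SplitSpec:
    """Train/test split policy.

    ``segment_random`` stratifies by class; ``subject_holdout`` keeps whole
    subjects out of training, emulating a blind test on unseen people.
    """

    mode: str = "segment_random"
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("segment_random", "subject_holdout"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


# -- sensor-log CSV contract ------------------------------------------------


def read_sensor_log(
    path,
    recording_id: str = "",
    subject_id: int = 0,
    class_id: int = 0,
    sample_rate_hz: float = 50.0,
) -> Recording:
    """Read one sensor-log CSV into a :class:`Recording`.

    Columns may appear in any order but must all be present; channel columns
    are returned in canonical order.
    """
    df = pd.read_csv(path)
    missing = [c for c in CHANNEL_NAMES if c not in df.columns]
    if missing:
        raise SensorLogFormatError(
            f"sensor log {path} is missing column(s): {', '.join(missing)}"
        )
    for col in CHANNEL_NAMES:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(np.flatnonzero(df[col].isna() | bad)[0])
            raise SensorLogFormatError(
                f"non-numeric value in column {col!r} at row {row}"
            )
    channels = df[list(CHANNEL_NAMES)].to_numpy(dtype=float)
    timestamps = None
    if "timestamp" in df.columns:
        timestamps = df["timestamp"].to_numpy(dtype=float)
        if np.any(np.diff(timestamps) <= 0):
            raise SensorLogFormatError("timestamps are not strictly increasing")
    return Recording(
        recording_id=recording_id or str(path),
        subject_id=subject_id,
        class_id=class_id,
        sample_rate_hz=sample_rate_hz,
        channels=channels,
        timestamps=timestamps,
    )


def write_sensor_log(recording: Recording, path) -> None:
    """Write a recording in the canonical CSV contract (9 significant digits)."""
    n = recording.n_samples
    ts = (
        recording.timestamps
        if recording.timestamps is not None
        else np.arange(n) / recording.sample_rate_hz
    )
    df = pd.DataFrame({"timestamp": ts})
    for j, name in enumerate(CHANNEL_NAMES):
        df[name] = recording.channels[:, j]
    df.to_csv(path, index=False, float_format="%.9g")


def read_manifest(path) -> pd.DataFrame:
    """Read the sidecar manifest (recording_id, subject_id, class_id, rate)."""
    df = pd.read_csv(path)
    required = {"recording_id", "subject_id", "class_id", "sample_rate_hz"}
    missing = required - set(df.columns)
    if missing:
        raise SensorLogFormatError(
            f"manifest missing column(s): {', '.join(sorted(missing))}"
        )
    return df


# -- preprocessing ----------------------------------------------------------

SD_EPS = 1e-12


def standardize(recording: Recording) -> Recording:
    """Per-channel zero-mean unit-variance scaling over one recording.

    Uses the population (divide-by-N) standard deviation so the transform is
    an exact closed form; channels with sd below ``SD_EPS`` become all zeros.
    """
    if recording.n_samples < 2:
        raise ValueError("standardization requires at least 2 samples")
    x = recording.channels
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population convention
    out = np.zeros_like(x)
    live = sd >= SD_EPS
    if not live.all():
        logger.warning(
            "recording %s: %d degenerate channel(s) mapped to zero",
            recording.recording_id,
            int((~live).sum()),
        )
    out[:, live] = (x[:, live] - mean[live]) / sd[live]
    return replace(recording, channels=out)


def standardize_global(recordings: list[Recording]) -> list[Recording]:
    """Pool all recordings for the channel statistics (alternative scope)."""
    stacked = np.concatenate([r.channels for r in recordings], axis=0)
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    live = sd >= SD_EPS
    out = []
    for r in recordings:
        x = np.zeros_like(r.channels)
        x[:, live] = (r.channels[:, live] - mean[live]) / sd[live]
        out.append(replace(r, channels=x))
    return out


def segment(
    recording: Recording, T: int, overlap_fraction: float = 0.0
) -> list[Segment]:
    """Cut a recording into full T-sample windows.

    Windows are half-open ``[start, start + T)`` starting at multiples of
    ``step = round(T * (1 - overlap_fraction))``; the trailing remainder is
    dropped.  A too-short recording yields an empty list.
    """
    if T < 2:
        raise ValueError("window length T must be >= 2")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    step = int(round(T * (1.0 - overlap_fraction)))
    step = max(step, 1)
    N = recording.n_samples
    if N < T:
        warnings.warn(
            f"recording {recording.recording_id}: {N} samples < window {T}; "
            "no segments emitted",
            stacklevel=2,
        )
        return []
    starts = range(0, N - T + 1, step)
    return [
        Segment(
            data=recording.channels[s : s + T].copy(),
            class_id=recording.class_id,
            subject_id=recording.subject_id,
            source_recording_id=recording.recording_id,
            start_index=s,
        )
        for s in starts
    ]


def build_segment_set(
    recordings: list[Recording],
    T: int,
    overlap_fraction: float = 0.0,
    class_vocabulary: list[str] | None = None,
    scope: str = "recording",
) -> SegmentSet:
    """Standardize then window a collection of recordings.

    ``scope`` selects the standardization statistics: per ``"recording"``
    (default) or ``"global"`` over the pooled collection.
    """
    if scope == "recording":
        recs = [standardize(r) for r in recordings]
    elif scope == "global":
        recs = standardize_global(recordings)
    else:
        raise ValueError(f"unknown standardization scope {scope!r}")
    segs: list[Segment] = []
    for r in recs:
        segs.extend(segment(r, T, overlap_fraction))
    if class_vocabulary is None:
        n_classes = max((r.class_id for r in recordings), default=-1) + 1
        class_vocabulary = [f"class_{i}" for i in range(n_classes)]
    return SegmentSet(segs, class_vocabulary)


def split(dataset: SegmentSet, spec: SplitSpec) -> tuple[SegmentSet, SegmentSet]:
    """Deterministic train/test partition of a segment set."""
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    labels = dataset.labels()
    n = len(dataset)

    if spec.mode == "segment_random":
        test_idx: list[int] = []
        train_idx: list[int] = []
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if members.size < 2:
                raise ValueError(
                    f"class {c} has {members.size} segment(s); "
                    "stratified split needs at least 2"
                )
            members = rng.permutation(members)
            n_test = int(round(spec.test_fraction * members.size))
            n_test = min(max(n_test, 1), members.size - 1)
            test_idx.extend(members[:n_test])
            train_idx.extend(members[n_test:])
        return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))

    # subject_holdout: whole subjects go to the test side until the target
    # segment fraction is reached (blind-test emulation).
    subjects = dataset.subjects()
    order = rng.permutation(np.unique(subjects))
    target = spec.test_fraction * n
    held: set[int] = set()
    count = 0
    for s in order:
        if count >= target:
            break
        held.add(int(s))
        count += int((subjects == s).sum())
    if len(held) == len(order):  # keep at least one training subject
        held.discard(int(order[-1]))
    test_idx = [i for i in range(n) if int(subjects[i]) in held]
    train_idx = [i for i in range(n) if int(subjects[i]) not in held]
    return dataset.subset(train_idx), dataset.subset(test_idx)
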