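"""Raw triaxial acceleration -> smoothed, windowed, 12-dimensional feature vectors.

A recording is one continuous session (typically a day) of wrist-worn
accelerometer samples.  The signal is smoothed with a causal moving-average
filter, cut into fixed-length overlapping windows, and each window is reduced
to 12 time-domain features: per-axis mean and variance, the three pairwise
axis correlations, and mean / variance / mean absolute first difference of
the acceleration magnitude.  Each window also carries a ground-truth activity
label obtained by majority vote of its samples against the labeled intervals;
time outside every interval belongs to the catch-all class ``not_tagged``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NOT_TAGGED = "not_tagged"

#: Fixed order of the per-window features.
FEATURE_NAMES = (
    "mean_x", "mean_y", "mean_z",
    "var_x", "var_y", "var_z",
    "corr_xy", "corr_xz", "corr_yz",
    "mean_mag", "var_mag", "avg_deriv_mag",
)

N_FEATURES = len(FEATURE_NAMES)


@dataclass
class TriaxialRecording:
    """Timestamped x/y/z acceleration samples (in g) for one run."""

    run_id: str
    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.timestamps)
        if n == 0:
            raise ValueError("empty input")
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("timestamps, x, y, z must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class LabeledInterval:
    """Half-open labeled time interval [start, end) on the recording clock."""

    start: float
    end: float
    activity: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"interval end must exceed start: {self}")


@dataclass
class ActivityLabeling:
    """Ordered, non-overlapping labeled intervals; gaps are ``not_tagged``."""

    intervals: list[LabeledInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping intervals: {a} / {b}")
        self.intervals = ivs


@dataclass
class PreprocessConfig:
    """Smoothing and windowing parameters.

    ``smoothing_n`` is the causal average-filter length (samples),
    ``window_length`` the window size l (samples), and ``overlap_fraction``
    the fractional overlap between consecutive windows.  The window step is
    ``l - round(overlap_fraction * l)`` (l=60, 0.33 -> step 40).
    """

    smoothing_n: int = 10
    window_length: int = 60
    overlap_fraction: float = 0.33

    def __post_init__(self) -> None:
        if self.smoothing_n < 1:
            raise ValueError("smoothing_n must be >= 1")
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.step < 1:
            raise ValueError("window step must be >= 1")

    @property
    def step(self) -> int:
        return self.window_length - round(self.overlap_fraction * self.window_length)


def smooth(signal: np.ndarray, n: int) -> np.ndarray:
    """Causal moving-average filter.

    For t with at least ``n`` preceding samples the output is the mean of the
    ``n`` samples strictly before t.  Earlier positions average all available
    preceding samples, and position 0 passes the raw sample through, so the
    output has the same length as the input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty input")
    if n < 1:
        raise ValueError("n must be >= 1")
    csum = np.concatenate(([0.0], np.cumsum(signal)))
    t = np.arange(signal.size)
    lo = np.maximum(t - n, 0)
    counts = np.maximum(t - lo, 1)          # position 0: avoid /0, fixed below
    out = (csum[t] - csum[lo]) / counts
    out[0] = signal[0]
    return out


def window_starts(n_samples: int, window_length: int, step: int) -> np.ndarray:
    """Start indices of full windows: 0, step, 2*step, ... with start+l <= n."""
    if n_samples < window_length:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - window_length + 1, step)


def sample_labels(recording: TriaxialRecording, labeling: ActivityLabeling) -> np.ndarray:
    """Per-sample activity label; samples outside every interval -> not_tagged."""
    labels = np.full(len(recording), NOT_TAGGED, dtype=object)
    ts = recording.timestamps
    for iv in labeling.intervals:
        mask = (ts >= iv.start) & (ts < iv.end)
        labels[mask] = iv.activity
    return labels


def _majority_label(window_labels: np.ndarray) -> str:
    """Majority by sample count; ties go to the label appearing first in time."""
    uniq, first_pos, counts = np.unique(
        window_labels, return_index=True, return_counts=True
    )
    best = counts.max()
    contenders = first_pos[counts == best]
    return str(window_labels[contenders.min()])


def make_windows(
    recording: TriaxialRecording,
    labeling: ActivityLabeling,
    config: PreprocessConfig,
) -> list[tuple[int, int, str]]:
    """Half-open [start, end) window index ranges with majority labels.

    Trailing samples that do not fill a whole window are discarded.
    """
    l = config.window_length
    starts = window_starts(len(recording), l, config.step)
    labels = sample_labels(recording, labeling)
    return [(int(s), int(s + l), _majority_label(labels[s : s + l])) for s in starts]


def _is_constant(a: np.ndarray) -> np.ndarray:
    return a.max(axis=1) == a.min(axis=1)


def _var(a: np.ndarray) -> np.ndarray:
    """Rowwise population variance; exactly 0 for constant rows."""
    return np.where(_is_constant(a), 0.0, a.var(axis=1))


def _corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rowwise Pearson correlation of (W, l) arrays; zero-variance pairs -> 0."""
    degenerate = _is_constant(a) | _is_constant(b)
    am = a - a.mean(axis=1, keepdims=True)
    bm = b - b.mean(axis=1, keepdims=True)
    num = (am * bm).mean(axis=1)
    den = np.sqrt((am**2).mean(axis=1) * (bm**2).mean(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))


def _features_batch(xw: np.ndarray, yw: np.ndarray, zw: np.ndarray) -> np.ndarray:
    """12 features for a batch of windows given as (W, l) arrays."""
    mag = np.sqrt(xw**2 + yw**2 + zw**2)
    feats = np.column_stack(
        [
            xw.mean(axis=1), yw.mean(axis=1), zw.mean(axis=1),
            _var(xw), _var(yw), _var(zw),
            _corr(xw, yw), _corr(xw, zw), _corr(yw, zw),
            mag.mean(axis=1), _var(mag),
            np.abs(np.diff(mag, axis=1)).mean(axis=1),
        ]
    )
    return feats


def extract_features(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """12 features for one window (see :data:`FEATURE_NAMES` for the order).

    Variances are population variances (divide by l); the magnitude
    derivative feature is the mean absolute first difference; correlations
    involving a zero-variance axis are defined as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise ValueError("axes must have equal length")
    if len(x) < 2:
        raise ValueError("window too short")
    return _features_batch(x[None, :], y[None, :], z[None, :])[0]


def featurize_run(
    recording: TriaxialRecording,
    labeling: ActivityLabeling,
    config: PreprocessConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth, window and featurize one recording.

    Returns ``(features, labels, starts)`` where ``features`` is a
    (W, 12) array, ``labels`` holds the per-window majority activity and
    ``starts`` the window start sample indices.
    """
    config = config or PreprocessConfig()
    xs = smooth(recording.x, config.smoothing_n)
    ys = smooth(recording.y, config.smoothing_n)
    zs = smooth(recording.z, config.smoothing_n)
    l = config.window_length
    starts = window_starts(len(recording), l, config.step)
    if starts.size == 0:
        return np.empty((0, N_FEATURES)), np.empty(0, dtype=object), starts
    sw = np.lib.stride_tricks.sliding_window_view
    feats = _features_batch(sw(xs, l)[starts], sw(ys, l)[starts], sw(zs, l)[starts])
    per_sample = sample_labels(recording, labeling)
    labels = np.array(
        [_majority_label(per_sample[s : s + l]) for s in starts], dtype=object
    )
    return feats, labels, starts
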