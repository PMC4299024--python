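"""Leave-one-day-out evaluation of the full segmentation pipeline.

For each held-out day the codebook, all model tables, the duration array
and (optionally) the subclassing are re-estimated on the remaining days
only; the held-out day is decoded, subclass predictions are mapped back to
original classes, and position-level accuracy plus a pooled confusion
matrix are accumulated.  ``not_tagged`` counts as an ordinary class in both
the decoding and the accuracy denominator.  Two time-of-day baselines that
ignore the accelerometer entirely are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .preprocess import PreprocessConfig, featurize_run
from .quantize import PrimitiveQuantizer, PrimitiveSequence, quantize_run
from .segmenter import ActivitySegmenter
from .subclass import extract_instances, find_subclasses, fixed_subclasses, relabel_windows
from .synthgen import SyntheticDay

SUBCLASS_METHODS = ("none", "fixed", "silhouette", "pbm", "gdi33")


@dataclass
class PipelineConfig:
    """Everything one evaluation run depends on, seeds included."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_primitives: int = 300
    kmer_k: int = 2
    alpha: float = 1.0
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    method: str = "hmm_c"
    transition_mode: str = "learned"
    subclass_method: str = "none"
    subclass_fixed: dict[str, int] = field(default_factory=dict)
    subclass_max_k: int = 5
    time_bin_minutes: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subclass_method not in SUBCLASS_METHODS:
            raise ValueError(f"subclass_method must be one of {SUBCLASS_METHODS}")
        if self.method not in ("hmm", "hmm_c", "crf"):
            raise ValueError("method must be hmm, hmm_c or crf")


def synthetic_pipeline_config(**overrides) -> PipelineConfig:
    """Pipeline configuration scaled to the synthetic default scenario.

    An hour-long synthetic day carries ~6 motion regimes, so a 24-primitive
    alphabet is ample and keeps the 2-mer table well estimated; all other
    parameters keep their defaults.
    """
    cfg = PipelineConfig(n_primitives=24)
    return replace(cfg, **overrides)


@dataclass
class EvaluationResult:
    """Per-fold accuracies and the pooled (truth x prediction) confusion."""

    classes: list[str]
    per_day_accuracy: list[float]
    confusion: pd.DataFrame

    @property
    def accuracy(self) -> float:
        """Pooled accuracy: trace of the confusion counts over their total."""
        counts = self.confusion.to_numpy()
        return float(np.trace(counts) / counts.sum())


def confusion_frame(y_true, y_pred, classes: list[str]) -> pd.DataFrame:
    counts = _sk_confusion(y_true, y_pred, labels=classes)
    return pd.DataFrame(counts, index=classes, columns=classes)


def sensitivity(confusion: pd.DataFrame) -> pd.Series:
    """Per-class true-positive rate; empty rows are reported as NaN."""
    counts = confusion.to_numpy(dtype=float)
    rows = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(rows > 0, np.diag(counts) / np.where(rows > 0, rows, 1.0), np.nan)
    return pd.Series(tpr, index=confusion.index, name="sensitivity")


def _featurize_days(days, config: PipelineConfig):
    feats, labels, starts = [], [], []
    for day in days:
        f, lab, st = featurize_run(day.recording, day.labeling, config.preprocess)
        feats.append(f)
        labels.append(lab)
        starts.append(st)
    return feats, labels, starts


def leave_one_day_out(
    days: list[SyntheticDay], config: PipelineConfig | None = None
) -> EvaluationResult:
    """Train on all days but one, decode the held-out day, pool results."""
    if len(days) < 2:
        raise ValueError("at least 2 runs required")
    config = config or PipelineConfig()
    feats, labels, _ = _featurize_days(days, config)
    all_classes = sorted({str(s) for lab in labels for s in lab})

    y_true_all, y_pred_all, per_day = [], [], []
    for i in range(len(days)):
        # canonical training order: results must not depend on how the list
        # of runs happened to be ordered
        train_idx = sorted(
            (j for j in range(len(days)) if j != i), key=lambda j: days[j].run_id
        )
        quantizer = PrimitiveQuantizer(
            n_primitives=config.n_primitives, random_state=config.seed
        ).fit(np.vstack([feats[j] for j in train_idx]))
        train_seqs = [
            quantize_run(quantizer, feats[j], labels[j], days[j].run_id)
            for j in train_idx
        ]
        test_seq = quantize_run(quantizer, feats[i], labels[i], days[i].run_id)

        mapping = None
        if config.subclass_method != "none":
            instances = extract_instances(train_seqs, config.n_primitives)
            if config.subclass_method == "fixed":
                submap = fixed_subclasses(instances, config.subclass_fixed, config.seed)
            else:
                submap = find_subclasses(
                    instances,
                    index=config.subclass_method,
                    max_k=config.subclass_max_k,
                    seed=config.seed,
                )
            new_labels = relabel_windows(train_seqs, instances, submap)
            train_seqs = [
                PrimitiveSequence(s.run_id, s.primitives, lab)
                for s, lab in zip(train_seqs, new_labels)
            ]
            mapping = submap.mapping

        seg = ActivitySegmenter(
            method=config.method,
            n_symbols=config.n_primitives,
            kmer_k=config.kmer_k,
            alpha=config.alpha,
            weights=config.weights,
            transition_mode=config.transition_mode,
        ).fit(train_seqs)
        pred = seg.predict(test_seq)
        if mapping is not None:
            pred = np.array([mapping.get(str(p), str(p)) for p in pred], dtype=object)
        truth = test_seq.labels
        per_day.append(float((pred == truth).mean()))
        y_true_all.append(truth)
        y_pred_all.append(pred)

    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    classes = sorted(set(all_classes) | {str(p) for p in y_pred})
    return EvaluationResult(
        classes=classes,
        per_day_accuracy=per_day,
        confusion=confusion_frame(y_true, y_pred, classes),
    )


# ---------------------------------------------------------------------------
# time-of-day baselines
# ---------------------------------------------------------------------------

def _window_time_bins(days, config: PipelineConfig):
    """Clock-time bin index of every window start, plus the window labels."""
    feats, labels, starts = _featurize_days(days, config)
    bin_s = config.time_bin_minutes * 60.0
    n_bins = int(np.ceil(86400.0 / bin_s))
    bins, labs = [], []
    for day, st in zip(days, starts):
        ts = day.recording.timestamps[st]
        bins.append(((ts % 86400.0) // bin_s).astype(int))
    return bins, labels, n_bins


def time_of_day_baseline(
    days: list[SyntheticDay],
    mode: str = "argmax",
    config: PipelineConfig | None = None,
) -> float:
    """Leave-one-day-out accuracy using clock time only.

    ``argmax`` predicts the training-majority activity of each time bin;
    ``hmm`` decodes the day with plain Viterbi on an HMM whose observations
    are the time bins.
    """
    if mode not in ("argmax", "hmm"):
        raise ValueError("mode must be 'argmax' or 'hmm'")
    if len(days) < 2:
        raise ValueError("at least 2 runs required")
    config = config or PipelineConfig()
    bins, labels, n_bins = _window_time_bins(days, config)

    correct = total = 0
    for i in range(len(days)):
        train_idx = [j for j in range(len(days)) if j != i]
        if mode == "argmax":
            classes = sorted({str(s) for j in train_idx for s in labels[j]})
            cindex = {c: k for k, c in enumerate(classes)}
            table = np.zeros((n_bins, len(classes)))
            for j in train_idx:
                for b, lab in zip(bins[j], labels[j]):
                    table[b, cindex[str(lab)]] += 1
            global_major = int(table.sum(axis=0).argmax())
            per_bin = np.where(
                table.sum(axis=1) > 0, table.argmax(axis=1), global_major
            )
            pred = np.array([classes[per_bin[b]] for b in bins[i]], dtype=object)
        else:
            seg = ActivitySegmenter(method="hmm", n_symbols=n_bins, alpha=config.alpha)
            seg.fit([bins[j] + 1 for j in train_idx], [labels[j] for j in train_idx])
            pred = seg.predict(bins[i] + 1)
        correct += int((pred == labels[i]).sum())
        total += len(labels[i])
    return correct / total
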