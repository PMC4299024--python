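"""Sequence-model parameter estimation from labeled primitive sequences.

One :class:`SequenceModel` carries everything both decoders need: the N x N
state-transition matrix A, the N x M emission matrix B, the uniform initial
distribution pi, a per-state k-mer (length-k substring) conditional frequency
table, the per-state minimum run-length array kappa, and the three feature
weights of the linear-chain CRF scoring.  All tables are estimated by
counting with additive (Laplace) smoothing ``alpha``; smoothing keeps the
log-domain scores finite when unseen primitives or k-mers appear at test
time, which is certain for large alphabets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .quantize import PrimitiveSequence

Kmer = tuple[int, ...]


@dataclass
class SequenceModel:
    """Estimated tables shared by HMM and CRF decoding.

    ``kmer_logp[i]`` maps observed k-mers (tuples of primitive IDs) to their
    smoothed log conditional probability under state i; k-mers absent from
    the table share the state's ``kmer_default_logp[i]``.  The table is kept
    sparse because M^k entries (90,000 at M=300, k=2) are mostly unobserved.
    """

    states: list[str]
    M: int
    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray
    kmer_k: int = 2
    kmer_logp: list[dict[Kmer, float]] = field(default_factory=list)
    kmer_default_logp: np.ndarray | None = None
    kappa: np.ndarray | None = None
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = len(self.states)
        if self.A.shape != (n, n) or self.B.shape != (n, self.M):
            raise ValueError("table shapes inconsistent with states/M")
        if self.kappa is None:
            self.kappa = np.ones(n, dtype=int)
        self.kappa = np.asarray(self.kappa, dtype=int)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        try:
            return self.states.index(name)
        except ValueError:
            raise KeyError(f"unknown state {name!r}") from None

    def kmer_log_prob(self, state_idx: int, kmer: Kmer) -> float:
        """Smoothed log P(k-mer | state); unobserved k-mers get the default."""
        table = self.kmer_logp[state_idx]
        default = float(self.kmer_default_logp[state_idx])
        return table.get(tuple(int(v) for v in kmer), default)


def _as_label_arrays(
    train: Sequence[PrimitiveSequence] | Sequence[np.ndarray],
) -> list[np.ndarray]:
    out = []
    for item in train:
        labels = item.labels if isinstance(item, PrimitiveSequence) else item
        out.append(np.asarray(labels, dtype=object))
    return out


def _as_primitive_arrays(train: Sequence) -> list[np.ndarray]:
    out = []
    for item in train:
        prims = item.primitives if isinstance(item, PrimitiveSequence) else item
        out.append(np.asarray(prims, dtype=int))
    return out


def estimate_emissions(
    train: Sequence[PrimitiveSequence],
    states: Sequence[str],
    M: int,
    alpha: float = 1.0,
) -> np.ndarray:
    """Additively smoothed per-state primitive frequencies (rows sum to 1)."""
    states = list(states)
    prims = _as_primitive_arrays(train)
    labels = _as_label_arrays(train)
    counts = np.zeros((len(states), M))
    index = {s: i for i, s in enumerate(states)}
    for p, lab in zip(prims, labels):
        for s, i in index.items():
            mask = lab == s
            if mask.any():
                counts[i] += np.bincount(p[mask] - 1, minlength=M)[:M]
    totals = counts.sum(axis=1)
    for s, i in index.items():
        if totals[i] == 0:
            raise ValueError(f"state {s!r} absent from training labels")
    return (counts + alpha) / (totals[:, None] + alpha * M)


def estimate_transitions(
    train: Sequence[PrimitiveSequence],
    states: Sequence[str],
    alpha: float = 1.0,
    mode: str = "learned",
) -> tuple[np.ndarray, np.ndarray]:
    """Transition matrix A from adjacent label pairs, and uniform pi.

    ``mode='uniform'`` replaces the learned matrix with 1/N everywhere
    (the no-information ablation); pi is always uniform.
    """
    states = list(states)
    n = len(states)
    pi = np.full(n, 1.0 / n)
    if mode == "uniform":
        return np.full((n, n), 1.0 / n), pi
    if mode != "learned":
        raise ValueError(f"unknown transition mode {mode!r}")
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((n, n))
    for lab in _as_label_arrays(train):
        for a, b in zip(lab[:-1], lab[1:]):
            counts[index[a], index[b]] += 1
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        A = (counts + alpha) / (row + alpha * n)
    # a state never followed by anything (e.g. only at run ends) with alpha=0:
    # fall back to uniform rather than an all-zero row
    bad = ~np.isfinite(A.sum(axis=1)) | (A.sum(axis=1) == 0)
    A[bad] = 1.0 / n
    return A, pi


def count_kmers(text: Sequence, pattern: Sequence) -> int:
    """Occurrences of ``pattern`` in ``text``, counting overlaps.

    Works on strings and on sequences of primitive IDs alike.
    """
    if len(pattern) == 0:
        raise ValueError("empty pattern")
    k = len(pattern)
    pat = tuple(pattern)
    return sum(1 for i in range(len(text) - k + 1) if tuple(text[i : i + k]) == pat)


def _concat_per_state(
    train: Sequence[PrimitiveSequence], states: Sequence[str]
) -> dict[str, np.ndarray]:
    """PrimSeq_i: concatenation of the primitives of every episode of state i."""
    prims = _as_primitive_arrays(train)
    labels = _as_label_arrays(train)
    out: dict[str, list[np.ndarray]] = {s: [] for s in states}
    for p, lab in zip(prims, labels):
        for s in states:
            mask = lab == s
            if mask.any():
                out[s].append(p[mask])
    return {
        s: (np.concatenate(parts) if parts else np.empty(0, dtype=int))
        for s, parts in out.items()
    }


def estimate_kmer_table(
    train: Sequence[PrimitiveSequence],
    states: Sequence[str],
    k: int,
    M: int,
    alpha: float = 1.0,
) -> tuple[list[dict[Kmer, float]], np.ndarray]:
    """Per-state smoothed k-mer conditional log-probabilities.

    For state i with concatenated primitive string PrimSeq_i, each of the
    M^k possible k-mers gets probability
    ``(count + alpha) / (|PrimSeq_i| - k + 1 + alpha * M**k)``; only observed
    k-mers are stored, all others share the state's default log-probability.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    concat = _concat_per_state(train, states)
    tables: list[dict[Kmer, float]] = []
    defaults = np.empty(len(list(states)))
    for i, s in enumerate(states):
        seq = concat[s]
        if len(seq) < k:
            raise ValueError(f"state {s!r} has fewer than k={k} primitives")
        n_pos = len(seq) - k + 1
        counts: dict[Kmer, int] = {}
        view = np.lib.stride_tricks.sliding_window_view(seq, k)
        for row in view:
            key = tuple(int(v) for v in row)
            counts[key] = counts.get(key, 0) + 1
        denom = n_pos + alpha * (M**k)
        with np.errstate(divide="ignore"):
            tables.append(
                {km: float(np.log((c + alpha) / denom)) for km, c in counts.items()}
            )
            defaults[i] = np.log(alpha / denom) if alpha > 0 else -np.inf
    return tables, defaults


def estimate_kappa(
    train: Sequence[PrimitiveSequence], states: Sequence[str]
) -> np.ndarray:
    """Minimum-run-length constraint: floor(min consecutive count / 2), >= 1.

    The minimum number of consecutive positions each state occupies in the
    training labels is halved (to allow some deviance from the training
    durations) and clamped to at least 1.
    """
    states = list(states)
    min_run = {s: np.inf for s in states}
    for lab in _as_label_arrays(train):
        if len(lab) == 0:
            continue
        boundaries = np.flatnonzero(lab[:-1] != lab[1:]) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(lab)]))
        for s0, e0 in zip(starts, ends):
            s = lab[s0]
            if s in min_run:
                min_run[s] = min(min_run[s], e0 - s0)
    for s in states:
        if not np.isfinite(min_run[s]):
            raise ValueError(f"state {s!r} absent from training labels")
    return np.array([max(1, int(min_run[s] // 2)) for s in states], dtype=int)


def fit_sequence_model(
    train: Sequence[PrimitiveSequence],
    states: Sequence[str] | None = None,
    M: int | None = None,
    kmer_k: int = 2,
    alpha: float = 1.0,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    transition_mode: str = "learned",
    with_kmers: bool = True,
) -> SequenceModel:
    """Estimate every table of a :class:`SequenceModel` from labeled runs."""
    prims = _as_primitive_arrays(train)
    labels = _as_label_arrays(train)
    seqs = [
        PrimitiveSequence(run_id=str(i), primitives=p, labels=lab)
        for i, (p, lab) in enumerate(zip(prims, labels))
    ]
    if states is None:
        states = sorted({str(s) for lab in labels for s in lab})
    states = list(states)
    if M is None:
        M = int(max(p.max() for p in prims))
    B = estimate_emissions(seqs, states, M, alpha)
    A, pi = estimate_transitions(seqs, states, alpha, transition_mode)
    kappa = estimate_kappa(seqs, states)
    if with_kmers:
        kmer_logp, kmer_default = estimate_kmer_table(seqs, states, kmer_k, M, alpha)
    else:
        kmer_logp, kmer_default = [{} for _ in states], np.zeros(len(states))
    return SequenceModel(
        states=states,
        M=M,
        A=A,
        B=B,
        pi=pi,
        kmer_k=kmer_k,
        kmer_logp=kmer_logp,
        kmer_default_logp=kmer_default,
        kappa=kappa,
        weights=tuple(weights),
        alpha=alpha,
    )
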