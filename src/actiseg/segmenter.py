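"""Sklearn-style estimator wrapping table estimation and Viterbi decoding.

``ActivitySegmenter`` is fit on labeled primitive sequences (one per run)
and predicts a per-position activity label for new sequences.  Three
decoding methods mirror the experimental grid of the underlying study:

* ``hmm``   — plain Viterbi on the HMM tables;
* ``hmm_c`` — Viterbi with the per-state minimum-run-length constraint;
* ``crf``   — constrained Viterbi on the CRF scoring, which adds the k-mer
  sequence-pattern feature on top of the HMM terms.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import decode
from .models import fit_sequence_model
from .quantize import PrimitiveSequence

METHODS = ("hmm", "hmm_c", "crf")


class ActivitySegmenter(BaseEstimator):
    """Segment primitive sequences into activities by best-path decoding.

    Parameters
    ----------
    method : {'hmm', 'hmm_c', 'crf'}, default 'hmm_c'
        Decoding method; 'hmm_c' and 'crf' enforce the duration constraint.
    n_symbols : int or None
        Alphabet size M; inferred from the training data when None.
    kmer_k : int, default 2
        k-mer length of the CRF sequence-pattern feature.
    alpha : float, default 1.0
        Additive smoothing pseudocount for every estimated table.
    weights : 3-tuple of float, default (1, 1, 1)
        CRF feature weights (w1: emission, w2: transition, w3: k-mer).
    transition_mode : {'learned', 'uniform'}, default 'learned'
        'uniform' replaces the learned transition matrix with 1/N (ablation).

    Attributes
    ----------
    classes_ : list of str
        Activity names in model order (sorted unique training labels).
    model_ : SequenceModel
        All estimated tables (A, B, pi, k-mer table, kappa).
    """

    def __init__(
        self,
        method: str = "hmm_c",
        n_symbols: int | None = None,
        kmer_k: int = 2,
        alpha: float = 1.0,
        weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
        transition_mode: str = "learned",
    ):
        self.method = method
        self.n_symbols = n_symbols
        self.kmer_k = kmer_k
        self.alpha = alpha
        self.weights = weights
        self.transition_mode = transition_mode

    def fit(self, X: Sequence, y: Sequence | None = None):
        """Estimate all tables from labeled runs.

        ``X`` is a list of :class:`PrimitiveSequence` (then ``y`` is ignored)
        or a list of 1-D primitive-ID arrays with ``y`` a matching list of
        per-position label arrays.
        """
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if y is not None:
            X = [
                PrimitiveSequence(run_id=str(i), primitives=p, labels=lab)
                for i, (p, lab) in enumerate(zip(X, y))
            ]
        self.model_ = fit_sequence_model(
            X,
            M=self.n_symbols,
            kmer_k=self.kmer_k,
            alpha=self.alpha,
            weights=tuple(self.weights),
            transition_mode=self.transition_mode,
            with_kmers=(self.method == "crf"),
        )
        self.classes_ = list(self.model_.states)
        return self

    def decode(self, observations: np.ndarray) -> decode.DecodeResult:
        """Decode one primitive sequence; returns the path and its score."""
        check_is_fitted(self, "model_")
        if self.method == "hmm":
            return decode.viterbi(self.model_, observations, scoring="hmm")
        scoring = "crf" if self.method == "crf" else "hmm"
        return decode.constrained_viterbi(self.model_, observations, scoring=scoring)

    def predict(self, X):
        """Per-position labels for one sequence or a list of sequences."""
        check_is_fitted(self, "model_")
        single = isinstance(X, PrimitiveSequence) or (
            not isinstance(X, (list, tuple))
            and np.asarray(X, dtype=object).ndim == 1
        )
        runs = [X] if single else list(X)
        out = []
        for run in runs:
            obs = run.primitives if isinstance(run, PrimitiveSequence) else run
            out.append(self.decode(np.asarray(obs, dtype=int)).path)
        return out[0] if single else out

    def score(self, X, y) -> float:
        """Position-level accuracy over one or more labeled sequences."""
        single = not isinstance(X, (list, tuple))
        preds = self.predict(X)
        if single:
            preds, y = [preds], [y]
        correct = total = 0
        for p, truth in zip(preds, y):
            truth = np.asarray(truth, dtype=object)
            correct += int((p == truth).sum())
            total += len(truth)
        return correct / total
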