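"""Best-path decoding: Viterbi, duration-constrained Viterbi, HMM/CRF scoring.

Both scorings reduce to the same additive form over a path: an initial score
per state, a transition score per ordered state pair, and a per-position
emission-like score.  For the HMM these are log pi, log A and log B.  The
linear-chain CRF scoring sums three weighted feature functions:

* f1 = log P(o_t | q_t)                       (emission log-probability)
* f2 = log pi(q_1) at t=1, log A[q_{t-1}, q_t] after   (transition term)
* f3 = log P(o_t .. o_{t+k-1} | q_t)          (k-mer conditional frequency)

f3 depends only on the observations and the state at t, so it folds into the
emission term; it contributes 0 at the last k-1 positions where the k-mer
would run past the end of the sequence.  The CRF normalizer is never needed:
the argmax over paths is invariant to it.

The duration constraint requires every maximal run of state i — including
the first and last runs — to span at least kappa(i) positions.  It is
decoded exactly by dynamic programming over (state, capped run length)
pairs: a path may leave state i only once its current run has reached
kappa(i).  Brute-force enumeration oracles for both decoders are exported
for testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .models import SequenceModel


@dataclass
class DecodeResult:
    """A decoded state path (as state names) and its log-domain score."""

    path: np.ndarray
    score: float

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=object)


# ---------------------------------------------------------------------------
# score-table construction
# ---------------------------------------------------------------------------

def _safe_log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def _check_obs(model: SequenceModel, observations: np.ndarray) -> np.ndarray:
    obs = np.asarray(observations, dtype=int)
    if obs.size == 0:
        raise ValueError("empty observation sequence")
    if obs.min() < 1 or obs.max() > model.M:
        raise ValueError("primitive ID outside 1..M")
    return obs


def build_score_tables(
    model: SequenceModel, observations: np.ndarray, scoring: str = "hmm"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(init, trans, emit) additive score tables for the chosen scoring.

    ``init`` has shape (N,), ``trans`` (N, N) and ``emit`` (T, N); the score
    of a path q is ``init[q_1] + sum_t emit[t, q_t] + sum_t trans[q_{t-1}, q_t]``.
    """
    obs = _check_obs(model, observations)
    log_pi = _safe_log(model.pi)
    log_A = _safe_log(model.A)
    log_B = _safe_log(model.B)
    emit_hmm = log_B[:, obs - 1].T  # (T, N)
    if scoring == "hmm":
        return log_pi, log_A, emit_hmm
    if scoring != "crf":
        raise ValueError(f"unknown scoring {scoring!r}")
    w1, w2, w3 = model.weights
    k = model.kmer_k
    T, N = emit_hmm.shape
    f3 = np.zeros((T, N))
    if w3 != 0.0:
        for t in range(T - k + 1):
            kmer = tuple(int(v) for v in obs[t : t + k])
            f3[t] = [model.kmer_log_prob(i, kmer) for i in range(N)]
    return w2 * log_pi, w2 * log_A, w1 * emit_hmm + w3 * f3


def path_score(
    init: np.ndarray, trans: np.ndarray, emit: np.ndarray, path: np.ndarray
) -> float:
    """Additive score of one state-index path under given score tables."""
    path = np.asarray(path, dtype=int)
    s = float(init[path[0]]) + float(emit[np.arange(len(path)), path].sum())
    if len(path) > 1:
        s += float(trans[path[:-1], path[1:]].sum())
    return s


def _path_indices(model: SequenceModel, path) -> np.ndarray:
    return np.array([model.state_index(str(s)) for s in path], dtype=int)


def hmm_score(model: SequenceModel, observations, path) -> float:
    """Joint log-probability log P(O, Q) of a path of state names."""
    init, trans, emit = build_score_tables(model, observations, "hmm")
    return path_score(init, trans, emit, _path_indices(model, path))


def crf_score(model: SequenceModel, observations, path) -> float:
    """Unnormalized CRF log-score sum_t (w1 f1 + w2 f2 + w3 f3) of a path."""
    init, trans, emit = build_score_tables(model, observations, "crf")
    return path_score(init, trans, emit, _path_indices(model, path))


# ---------------------------------------------------------------------------
# decoders (integer-index level)
# ---------------------------------------------------------------------------

def viterbi_tables(
    init: np.ndarray, trans: np.ndarray, emit: np.ndarray
) -> tuple[np.ndarray, float]:
    """Unconstrained max-score path; ties resolved toward lower state index."""
    T, N = emit.shape
    delta = init + emit[0]
    psi = np.zeros((T, N), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + trans  # cand[i, j]
        psi[t] = cand.argmax(axis=0)  # first max -> lowest predecessor
        delta = cand[psi[t], np.arange(N)] + emit[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, float(delta.max())


def constrained_viterbi_tables(
    init: np.ndarray, trans: np.ndarray, emit: np.ndarray, kappa: np.ndarray
) -> tuple[np.ndarray, float]:
    """Max-score path whose every maximal run of state i has length >= kappa(i).

    DP cells are (state j, run length r) with r capped at kappa(j); a
    transition into a different state is allowed only from a cell at its cap,
    and the path must end in a cap cell so the final run also satisfies the
    constraint.
    """
    T, N = emit.shape
    kappa = np.asarray(kappa, dtype=int)
    if kappa.shape != (N,) or kappa.min() < 1:
        raise ValueError("kappa must hold positive integers, one per state")
    offsets = np.concatenate(([0], np.cumsum(kappa)))[:-1]
    K = int(kappa.sum())
    cell_state = np.concatenate([np.full(kappa[j], j) for j in range(N)])
    cap_cells = offsets + kappa - 1  # flat index of each state's cap cell

    NEG = -np.inf
    score = np.full(K, NEG)
    parent = np.full((T, K), -1, dtype=np.int32)
    score[offsets] = init + emit[0]  # run length 1 at t=0

    for t in range(1, T):
        caps = score[cap_cells]  # best score ending a completed run per state
        new = np.full(K, NEG)
        par = parent[t]
        for j in range(N):
            base = offsets[j]
            kj = kappa[j]
            stay = score[base : base + kj] + trans[j, j]
            if kj > 1:
                # grow the run: r -> r+1 (last source also feeds the cap)
                new[base + 1 : base + kj] = stay[:-1]
                par[base + 1 : base + kj] = np.arange(base, base + kj - 1)
                if stay[-1] > new[base + kj - 1]:
                    new[base + kj - 1] = stay[-1]
                    par[base + kj - 1] = base + kj - 1
                entry = caps + trans[:, j]
                entry[j] = NEG  # same-state continuation handled above
            else:
                # kappa == 1: self-loop also lands on the single cell
                entry = caps + trans[:, j]
            i_best = int(entry.argmax())
            if entry[i_best] > new[base]:
                new[base] = entry[i_best]
                par[base] = cap_cells[i_best]
            elif entry[i_best] == new[base] and np.isfinite(new[base]):
                # deterministic tie rule: prefer the lower predecessor state
                if cell_state[cap_cells[i_best]] < cell_state[par[base]]:
                    par[base] = cap_cells[i_best]
        score = new + emit[t][cell_state]

    finals = score[cap_cells]
    if not np.isfinite(finals.max()):
        raise ValueError("infeasible constraint for T")
    best_state = int(finals.argmax())
    cell = int(cap_cells[best_state])
    path = np.zeros(T, dtype=int)
    for t in range(T - 1, -1, -1):
        path[t] = cell_state[cell]
        if t > 0:
            cell = int(parent[t, cell])
    return path, float(finals.max())


def satisfies_min_run(path: np.ndarray, kappa: np.ndarray) -> bool:
    """True iff every maximal run (boundary runs included) meets kappa."""
    path = np.asarray(path)
    boundaries = np.flatnonzero(path[:-1] != path[1:]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(path)]))
    return all(e - s >= kappa[int(path[s])] for s, e in zip(starts, ends))


# ---------------------------------------------------------------------------
# model-level wrappers
# ---------------------------------------------------------------------------

def viterbi(model: SequenceModel, observations, scoring: str = "hmm") -> DecodeResult:
    """Unconstrained best state path under HMM or CRF scoring."""
    init, trans, emit = build_score_tables(model, observations, scoring)
    idx, score = viterbi_tables(init, trans, emit)
    return DecodeResult(path=np.array([model.states[i] for i in idx]), score=score)


def constrained_viterbi(
    model: SequenceModel, observations, scoring: str = "hmm"
) -> DecodeResult:
    """Best state path subject to the per-state minimum-run-length array."""
    init, trans, emit = build_score_tables(model, observations, scoring)
    idx, score = constrained_viterbi_tables(init, trans, emit, model.kappa)
    assert satisfies_min_run(idx, model.kappa), "decoded path violates kappa"
    return DecodeResult(path=np.array([model.states[i] for i in idx]), score=score)


# ---------------------------------------------------------------------------
# brute-force oracles (exponential; for testing at tiny T only)
# ---------------------------------------------------------------------------

def brute_force_best(
    init: np.ndarray,
    trans: np.ndarray,
    emit: np.ndarray,
    kappa: np.ndarray | None = None,
) -> tuple[np.ndarray, float, bool]:
    """Exhaustive argmax over all N^T paths, optionally run-length filtered.

    Returns ``(path, score, unique)`` where ``unique`` says whether the
    optimum is attained by a single path (within 1e-12).
    """
    T, N = emit.shape
    best_path, best_score, n_best = None, -np.inf, 0
    for cand in itertools.product(range(N), repeat=T):
        path = np.array(cand, dtype=int)
        if kappa is not None and not satisfies_min_run(path, kappa):
            continue
        s = path_score(init, trans, emit, path)
        if s > best_score + 1e-12:
            best_path, best_score, n_best = path, s, 1
        elif s > best_score - 1e-12:
            n_best += 1
    if best_path is None:
        raise ValueError("infeasible constraint for T")
    return best_path, best_score, n_best == 1
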