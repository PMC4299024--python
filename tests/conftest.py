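import numpy as np
import pytest

from actiseg.models import SequenceModel
from actiseg.synthgen import default_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Three short synthetic days shared by the cheaper integration tests."""
    return default_scenario(3, seed=42, day_length_s=1200)


@pytest.fixture
def toy_model():
    """Two-state, two-symbol model with hand-set tables (no smoothing)."""
    return SequenceModel(
        states=["a", "b"],
        M=2,
        A=np.array([[0.9, 0.1], [0.1, 0.9]]),
        B=np.array([[0.8, 0.2], [0.2, 0.8]]),
        pi=np.array([0.5, 0.5]),
        kmer_k=2,
        kmer_logp=[{}, {}],
        kmer_default_logp=np.log(np.array([0.25, 0.25])),
        kappa=np.array([1, 1]),
        alpha=0.0,
    )


def random_model(rng, n_states=2, M=3, kappa_max=1, kmer_k=2):
    """Random stochastic tables for oracle comparisons."""
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    B = rng.dirichlet(np.ones(M), size=n_states)
    pi = rng.dirichlet(np.ones(n_states))
    kmers = {}
    tables = []
    defaults = np.empty(n_states)
    for i in range(n_states):
        probs = rng.dirichlet(np.ones(M**kmer_k))
        keys = [
            tuple(int(v) + 1 for v in np.unravel_index(j, (M,) * kmer_k))
            for j in range(M**kmer_k)
        ]
        tables.append({k: float(np.log(p)) for k, p in zip(keys, probs)})
        defaults[i] = -np.inf
    kappa = rng.integers(1, kappa_max + 1, size=n_states)
    return SequenceModel(
        states=[f"s{i}" for i in range(n_states)],
        M=M,
        A=A,
        B=B,
        pi=pi,
        kmer_k=kmer_k,
        kmer_logp=tables,
        kmer_default_logp=defaults,
        kappa=kappa,
        alpha=0.0,
    )
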