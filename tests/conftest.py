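"""Shared fixtures and independent oracles.

The enumeration oracles below compute HMM quantities by explicit
summation/maximisation over every state path, using the dense transition
matrix formula directly — deliberately independent of the scaled O(K)
recursions in the package.
"""

import itertools

import numpy as np
import pytest
from hypothesis import settings

import mosaicf as mf

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


# ----------------------------------------------------------------------
# Enumeration oracles
# ----------------------------------------------------------------------

def dense_transition(d, rates, pi):
    stay = np.exp(-np.asarray(rates) * d)
    return np.diag(stay) + (1.0 - stay)[:, None] * np.asarray(pi)[None, :]


def enum_posteriors(emis, dists, rates, pi):
    """Posterior state marginals and log-likelihood by explicit path sum."""
    T, S = emis.shape
    trans = [dense_transition(d, rates, pi) for d in dists]
    marginal = np.zeros((T, S))
    total = 0.0
    for path in itertools.product(range(S), repeat=T):
        p = pi[path[0]] * emis[0, path[0]]
        for t in range(T - 1):
            p *= trans[t][path[t], path[t + 1]] * emis[t + 1, path[t + 1]]
        total += p
        for t, s in enumerate(path):
            marginal[t, s] += p
    return marginal / total, np.log(total)


def enum_viterbi(emis, dists, rates, pi):
    """Most probable path by exhaustive search (lexicographically first
    among exact ties)."""
    T, S = emis.shape
    trans = [dense_transition(d, rates, pi) for d in dists]
    best, best_path = -np.inf, None
    for path in itertools.product(range(S), repeat=T):
        p = pi[path[0]] * emis[0, path[0]]
        for t in range(T - 1):
            p *= trans[t][path[t], path[t + 1]] * emis[t + 1, path[t + 1]]
        if p > best:
            best, best_path = p, path
    return np.array(best_path), np.log(best) if best > 0 else -np.inf


def random_small_instance(seed, n_markers=6, k_hbd=2):
    """A small random chain: config, map, freqs, genotypes."""
    rng = np.random.default_rng(seed)
    config = mf.HBDModelConfig(hbd_rates=(4.0, 16.0)[:k_hbd],
                               nonhbd_rate=64.0, error=0.002)
    bp = np.sort(rng.choice(np.arange(1, 60_000_000), size=n_markers,
                            replace=False))
    mm = mf.MarkerMap(np.array(["chr1"] * n_markers, dtype=object),
                      np.array([f"m{i}" for i in range(n_markers)],
                               dtype=object),
                      bp, bp / 1e6)
    freqs = rng.uniform(0.2, 0.8, n_markers)
    genotypes = rng.choice([0, 1, 2, -1], size=n_markers,
                           p=[0.3, 0.3, 0.3, 0.1])
    return config, mm, freqs, genotypes


def emission_table(genotypes, freqs, config):
    """Dense (T, S) emission matrix from the scalar emission op."""
    K = config.n_classes - 1
    T = len(genotypes)
    emis = np.empty((T, K + 1))
    for t in range(T):
        for s in range(K + 1):
            emis[t, s] = mf.emission_probability(int(genotypes[t]),
                                                 float(freqs[t]),
                                                 config.error, hbd=s < K)
    return emis


def chain_distances(mm, config):
    morg = mm.morgans(config.cm_per_mb)
    return np.maximum(np.diff(morg), 1e-8)


# ----------------------------------------------------------------------
# Fixtures
# ----------------------------------------------------------------------

@pytest.fixture
def toy_map():
    bp = np.array([0, 10_000_000, 20_000_000, 30_000_000, 99_999_999])
    return mf.MarkerMap(np.array(["chr1"] * 5, dtype=object),
                        np.array([f"m{i}" for i in range(5)], dtype=object),
                        bp, bp / 1e6)


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-individual cohort with recent (R=4) inbreeding, no deletions."""
    rates = (4.0, 2048.0)
    cfg = mf.SimulationConfig(
        n_individuals=5,
        chromosomes=[(f"chr{i}", 50_000_000) for i in range(1, 9)],
        marker_density=25.0,
        class_rates=rates,
        mixing_proportions=tuple(mf.mixing_for_autozygosity(0.2, rates)),
        seed=11,
    )
    return mf.simulate_dataset(cfg)
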