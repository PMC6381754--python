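"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths they check:
the exact rank-sum p enumerates all rank assignments, the AUC oracle
counts pairwise wins with a double loop, and the Youden oracle scans
every candidate threshold including -inf.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

import methsig as m


# ---------------------------------------------------------------------------
# oracles

def exact_ranksum_p(a, b):
    """Two-sided exact rank-sum p by full enumeration of C(n, n_a) splits."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    n, na = len(pooled), len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties assumed
    obs = sum(ranks[v] for v in a)
    mean_w = na * (n + 1) / 2.0
    count = total = 0
    for combo in itertools.combinations(range(1, n + 1), na):
        w = sum(combo)
        total += 1
        if abs(w - mean_w) >= abs(obs - mean_w) - 1e-9:
            count += 1
    return count / total


def pairwise_auc(pos, neg):
    """AUC by explicit double loop: wins count 1, ties 0.5."""
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else 0.5 if p == q else 0.0
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, labels):
    """Best (J, smallest cutoff) over every threshold including -inf."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    best_j, best_c = -np.inf, None
    for c in sorted([-np.inf] + sorted(set(scores))):
        sens = float((pos > c).mean())
        spec = float((neg <= c).mean())
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return best_j, best_c


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_manifest():
    return m.generate_manifest(10, 8, 0.5, seed=1)


@pytest.fixture(scope="session")
def planted_genes():
    return [
        m.PlantedGene("GENE0001", "hyper_in_R", 0.30, n_consecutive_cpgs=4,
                      sd_within=0.10),
        m.PlantedGene("GENE0002", "hyper_in_NR", 0.30, n_consecutive_cpgs=4,
                      sd_within=0.10),
    ]


@pytest.fixture(scope="session")
def planted_cohort(small_manifest, planted_genes):
    return m.generate_cohort(small_manifest, 12, 12, planted_genes, seed=7)


@pytest.fixture()
def demo_config():
    from methsig.io import PipelineConfig

    return PipelineConfig(seed=11)
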