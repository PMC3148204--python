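"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain Python loops and first-principles
enumeration so they stay independent of the vectorised implementation paths
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from decurve import PredictionSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_prediction_set(rng: np.random.Generator, n: int, label: str = "random") -> PredictionSet:
    """Random continuous probabilities with both outcome classes guaranteed."""
    p = rng.uniform(0.0, 1.0, n)
    y = rng.binomial(1, 0.5, n)
    y[0], y[1] = 1, 0  # ensure both classes
    return PredictionSet(outcomes=y, probabilities=p, label=label)


def brute_classify(outcomes, probabilities, p_t):
    """Count the four cells one subject at a time (oracle for classify)."""
    a = b = c = d = 0
    for y, p in zip(outcomes, probabilities):
        if p > p_t:
            if y == 1:
                a += 1
            else:
                b += 1
        else:
            if y == 1:
                c += 1
            else:
                d += 1
    n = len(outcomes)
    return a / n, b / n, c / n, d / n


def enumerate_classifications(outcomes, probabilities):
    """All achievable (sensitivity, specificity) pairs under 'treat if p > t'.

    Scans every distinct treated set: subjects are sorted by probability
    descending and treated in tie-grouped prefixes, which enumerates exactly
    the classifications any cutoff can induce.
    """
    order = sorted(range(len(outcomes)), key=lambda i: -probabilities[i])
    n_pos = sum(outcomes)
    n_neg = len(outcomes) - n_pos
    pairs = [(0.0, 1.0)]  # nobody treated
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and probabilities[order[j]] == probabilities[order[i]]:
            if outcomes[order[j]] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        pairs.append((tp / n_pos, 1.0 - fp / n_neg))
        i = j
    return pairs  # (sensitivity, specificity), treated set growing
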