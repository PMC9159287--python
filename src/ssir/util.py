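"""Small shared utilities."""

from __future__ import annotations

import numpy as np

__all__ = ["adjusted_rand_index"]


def adjusted_rand_index(labels_true, labels_pred) -> float:
    """Chance-corrected Rand index between two labelings of the same items.

    ARI = (sum_ij C(n_ij,2) - E) / (max - E) with the usual hypergeometric
    expectation; 1 for identical partitions, ~0 for independent ones.
    """
    a = np.asarray(labels_true)
    b = np.asarray(labels_pred)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        x = np.asarray(x, dtype=np.float64)
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
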