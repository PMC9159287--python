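"""Numba kernels for fast per-group statistics inside the GA loop.

Observations are pre-sorted by dataset so a group evaluation only touches the
member datasets' slices.  Per-reflection counts and sums are assembled from
per-dataset dense aggregates outside numba; the only raw-observation pass
left is the absolute-deviation sum that the R factors need.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def deviation_sums(uid, i_obs, ds_offsets, members, n, mean_i, n_unique):
    """dev[u] = sum over group observations of |I - mean_i[u]| for n[u] >= 2."""
    dev = np.zeros(n_unique, dtype=np.float64)
    for mi in range(members.shape[0]):
        m = members[mi]
        for i in range(ds_offsets[m], ds_offsets[m + 1]):
            u = uid[i]
            if n[u] > 1:
                dev[u] += abs(i_obs[i] - mean_i[u])
    return dev


@njit(cache=True)
def dataset_aggregates(uid, i_obs, w_obs, ds_offsets, n_datasets, n_unique):
    """Per-dataset dense (n, sum I, sum w, sum wI) matrices, shape (D, U)."""
    m_n = np.zeros((n_datasets, n_unique), dtype=np.float64)
    m_i = np.zeros((n_datasets, n_unique), dtype=np.float64)
    m_w = np.zeros((n_datasets, n_unique), dtype=np.float64)
    m_wi = np.zeros((n_datasets, n_unique), dtype=np.float64)
    for d in range(n_datasets):
        for i in range(ds_offsets[d], ds_offsets[d + 1]):
            u = uid[i]
            m_n[d, u] += 1.0
            m_i[d, u] += i_obs[i]
            m_w[d, u] += w_obs[i]
            m_wi[d, u] += w_obs[i] * i_obs[i]
    return m_n, m_i, m_w, m_wi
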