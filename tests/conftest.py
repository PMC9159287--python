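"""Shared fixtures: hand-built observation tables and small synthetic pools."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ssir.cells import UnitCell
from ssir.io import ObservationTable
from ssir.simulate import PoolSpec, simulate_pool
from ssir.symmetry import get_symmetry


def make_table(records, cell=None, symbol="P1", cells=None):
    """ObservationTable from (dataset_id, h, k, l, I, sigma) tuples."""
    df = pd.DataFrame(records, columns=["dataset_id", "h", "k", "l", "intensity", "sigma"])
    if cells is None:
        cell = cell or UnitCell(20.0, 20.0, 20.0)
        cells = {d: cell for d in df["dataset_id"].unique()}
    return ObservationTable(df, cells, get_symmetry(symbol))


def random_pool(rng, n_datasets=4, n_unique=40, max_mult=4, cell=None, symbol="P1"):
    """Random small pool for oracle comparisons (no physics, pure bookkeeping)."""
    cell = cell or UnitCell(12.0, 13.0, 14.0, 88.0, 95.0, 102.0)
    sym = get_symmetry(symbol)
    # draw unique reflections from a shell that the cell supports
    hkl = rng.integers(-4, 5, size=(n_unique, 3))
    hkl = hkl[np.any(hkl != 0, axis=1)]
    records = []
    base_i = rng.gamma(2.0, 50.0, size=len(hkl))
    for d in range(n_datasets):
        ds = f"ds{d:02d}"
        for j, (h, k, l) in enumerate(hkl):
            for _ in range(rng.integers(0, max_mult + 1)):
                i = base_i[j] * rng.lognormal(0, 0.1) + rng.normal(0, 2.0)
                s = rng.uniform(0.5, 5.0)
                records.append((ds, int(h), int(k), int(l), float(i), float(s)))
    if not records:
        records.append(("ds00", 1, 0, 0, 10.0, 1.0))
    return make_table(records, cell=cell, symbol=symbol)


@pytest.fixture(scope="session")
def tiny_pool():
    """6-dataset P1 pool with a clear native/derivative split (3 + 3)."""
    spec = PoolSpec(
        cell=UnitCell(30.0, 30.0, 30.0),
        space_group="P1",
        d_min=2.5,
        n_native=3,
        n_derivative=3,
        coverage_fraction=0.7,
        n_protein_atoms=30,
        seed=11,
    )
    return simulate_pool(spec)


@pytest.fixture(scope="session")
def small_p43_pool():
    """Small tetragonal pool exercising a non-trivial point group."""
    spec = PoolSpec(
        d_min=3.0,
        n_native=4,
        n_derivative=4,
        coverage_fraction=0.6,
        seed=23,
    )
    return simulate_pool(spec)
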