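"""Synthetic serial-crystallography pools with known native/derivative truth.

The simulator emulates the statistical structure of a serial SIR experiment:

* many partial datasets from microcrystals of one (point-atom) structure,
* two latent sub-populations whose heavy-atom occupancy distributions
  overlap (soaks partially derivatize the "native" crystals too),
* per-crystal unit-cell jitter producing resolution-dependent intensity
  non-isomorphism (rigid-contents model, see ``crick_magdoff_change``),
* partial reciprocal-space coverage and within-crystal multiplicity,
* per-crystal linear scales and counting-statistics noise.

It deliberately does NOT simulate detector geometry, rotation wedges,
absorption, radiation damage or anomalous scattering: grouping statistics
depend only on the coverage/multiplicity/noise distributions emulated here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cells import UnitCell, resolution
from .io import ObservationTable, write_pool
from .symmetry import SymmetrySetting, enumerate_unique, get_symmetry

__all__ = [
    "AtomSpec",
    "PoolSpec",
    "PoolTruth",
    "structure_factors",
    "crick_magdoff_change",
    "apply_non_isomorphism",
    "simulate_pool",
    "default_test_structure",
    "CRICK_MAGDOFF_CONSTANT",
]

# Mean fractional intensity change of acentric reflections when one cell edge
# of length a changes by fraction eps, atoms (uniform in a sphere of radius
# a/2) keeping their Cartesian positions: m = (2/sqrt(pi)) * (pi/sqrt(15)) *
# eps * a / d.  Reproduces the classical 0.5% -> ~15% @ 3 A estimate.
CRICK_MAGDOFF_CONSTANT = float(2.0 / np.sqrt(np.pi) * np.pi / np.sqrt(15.0))


@dataclass(frozen=True)
class AtomSpec:
    """Point scatterer: fractional position, scattering weight f (electrons),
    isotropic B (A^2), occupancy."""

    x: float
    y: float
    z: float
    f: float
    b: float = 15.0
    occupancy: float = 1.0
    kind: str = "protein"  # "protein" | "heavy"

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("scattering weight must be positive")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z]) % 1.0


def default_test_structure(
    n_protein: int = 120,
    protein_f: float = 7.0,
    protein_b: float = 15.0,
    heavy_sites: Sequence[tuple[float, float, float]] = ((0.23, 0.31, 0.17), (0.68, 0.12, 0.45)),
    heavy_f: float = 60.0,
    heavy_b: float = 15.0,
    seed: int = 7,
) -> tuple[list[AtomSpec], list[AtomSpec]]:
    """A reproducible toy structure: random protein atoms + fixed heavy sites."""
    rng = np.random.default_rng(seed)
    xyz = rng.random((n_protein, 3))
    protein = [AtomSpec(*p, f=protein_f, b=protein_b) for p in xyz]
    heavy = [AtomSpec(*s, f=heavy_f, b=heavy_b, kind="heavy") for s in heavy_sites]
    return protein, heavy


def structure_factors(
    atoms: Sequence[AtomSpec],
    cell: UnitCell,
    sym: SymmetrySetting,
    hkl: np.ndarray = None,
    d_min: float = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Space-group-expanded structure factors F(h) on the unique set.

    F(h) = sum_ops sum_j f_j occ_j exp(-B_j/(4 d^2)) exp(2 pi i h.(R x_j + t)).
    Returns (hkl, F) with F complex.  Either ``hkl`` or ``d_min`` must be given.
    """
    if not atoms:
        raise ValueError("no atoms")
    if hkl is None:
        if d_min is None:
            raise ValueError("either hkl or d_min required")
        hkl = enumerate_unique(cell, sym, d_min)
    hkl = np.asarray(hkl, dtype=np.int64)
    d = resolution(hkl, cell)
    xyz = np.array([a.position for a in atoms])          # (A,3)
    f = np.array([a.f * a.occupancy for a in atoms])     # (A,)
    b = np.array([a.b for a in atoms])                   # (A,)
    damp = np.exp(-np.outer(1.0 / (4.0 * d * d), b))     # (N,A)
    F = np.zeros(len(hkl), dtype=complex)
    for rot, trans in sym.spacegroup_operators():
        frac = xyz @ rot.T + trans                        # (A,3)
        phase = 2.0 * np.pi * (hkl @ frac.T)              # (N,A)
        F += np.sum(f * damp * np.exp(1j * phase), axis=1)
    return hkl, F


def crick_magdoff_change(epsilon: float, d: float, a: float) -> float:
    """Mean fractional intensity change of acentric reflections for a
    fractional change ``epsilon`` of one cell edge of length ``a`` (A),
    evaluated at resolution ``d`` (A), with the crystal contents held rigid.

    m = (2/sqrt(pi)) * (pi/sqrt(15)) * epsilon * a / d  (~0.9153 eps a/d)

    Outside the small-perturbation regime (eps*a/d > 0.5) a warning is
    emitted but the linear value is still returned.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if d <= 0 or a <= 0:
        raise ValueError("d and a must be positive")
    x = epsilon * a / d
    if x > 0.5:
        import warnings

        warnings.warn("cell change outside the small-perturbation regime; "
                      "linear estimate returned", stacklevel=2)
    return CRICK_MAGDOFF_CONSTANT * x


def apply_non_isomorphism(
    intensities: np.ndarray,
    epsilon: float,
    d: np.ndarray,
    a: float,
    rng=None,
) -> np.ndarray:
    """Stochastic resolution-dependent intensity perturbation.

    Each intensity is multiplied by (1 + m(eps, d_hkl, a) * z) where z is a
    zero-mean Gaussian scaled by sqrt(pi/2), so that the expected |dI|/I at
    resolution d equals m(eps, d, a) (E|N(0,1)| = sqrt(2/pi)).  Results are
    clipped at zero.  ``rng`` is a numpy Generator or an integer seed.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if epsilon == 0:
        return np.asarray(intensities, dtype=float).copy()
    m = CRICK_MAGDOFF_CONSTANT * epsilon * a / np.asarray(d, dtype=float)
    z = rng.standard_normal(len(m)) * np.sqrt(np.pi / 2.0)
    out = np.asarray(intensities, dtype=float) * (1.0 + m * z)
    return np.maximum(out, 0.0)


@dataclass
class PoolSpec:
    """Stated world of one synthetic pool (defaults: the reference pool)."""

    cell: UnitCell = field(default_factory=lambda: UnitCell(78.0, 78.0, 38.5, 90.0, 90.0, 90.0))
    space_group: str = "P43212"
    d_min: float = 2.0
    n_native: int = 30
    n_derivative: int = 30
    occupancy_native: tuple[float, float] = (0.05, 0.05)      # (mean, sd), clipped to [0,1]
    occupancy_derivative: tuple[float, float] = (0.70, 0.15)
    cell_jitter_sd: float = 0.001        # fractional per-axis jitter
    cell_offset_native: float = 0.0      # fractional offset of the group cell centre
    cell_offset_derivative: float = 0.0
    coverage_fraction: float = 0.5       # P(unique reflection observed) per crystal
    mean_multiplicity: float = 2.0       # within-crystal obs per seen reflection
    mean_counts: float = 100.0           # pool-mean intensity in detector counts
    noise_floor: float = 25.0            # additive variance floor (counts^2)
    counting_noise: bool = True
    scale_sd: float = 0.2                # lognormal sd of per-crystal scales
    seed: int = 1
    structure_seed: int = 7
    n_protein_atoms: int = 120
    heavy_sites: tuple = ((0.23, 0.31, 0.17), (0.68, 0.12, 0.45))
    heavy_f: float = 60.0
    protein_f: float = 7.0
    atom_b: float = 15.0

    def __post_init__(self) -> None:
        if self.n_native < 0 or self.n_derivative < 0:
            raise ValueError("dataset counts must be non-negative")
        if not 0 < self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if self.mean_multiplicity < 1:
            raise ValueError("mean_multiplicity must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell"] = list(self.cell.as_tuple())
        d["heavy_sites"] = [list(s) for s in self.heavy_sites]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PoolSpec":
        d = dict(d)
        if "cell" in d and not isinstance(d["cell"], UnitCell):
            d["cell"] = UnitCell(*d["cell"])
        if "heavy_sites" in d:
            d["heavy_sites"] = tuple(tuple(s) for s in d["heavy_sites"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown PoolSpec keys: {sorted(unknown)}")
        for key in ("occupancy_native", "occupancy_derivative"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PoolTruth:
    """Ground truth of a simulated pool, for recovery tests."""

    table: pd.DataFrame            # dataset_id, label, occupancy, epsilon, scale
    heavy_positions: np.ndarray    # (n_sites, 3) fractional
    spec: PoolSpec

    def labels_for(self, dataset_ids: Sequence[str]) -> np.ndarray:
        lookup = dict(zip(self.table["dataset_id"], self.table["label"]))
        return np.array([lookup[d] for d in dataset_ids])

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "datasets": self.table.to_dict(orient="records"),
            "heavy_positions": self.heavy_positions.tolist(),
            "spec": self.spec.to_dict(),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path) -> "PoolTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            table=pd.DataFrame(payload["datasets"]),
            heavy_positions=np.array(payload["heavy_positions"]),
            spec=PoolSpec.from_dict(payload["spec"]),
        )


def simulate_pool(spec: PoolSpec) -> tuple[ObservationTable, PoolTruth]:
    """Simulate one pool of partial datasets; deterministic under spec.seed."""
    sym = get_symmetry(spec.space_group)
    protein, heavy = default_test_structure(
        n_protein=spec.n_protein_atoms,
        protein_f=spec.protein_f,
        protein_b=spec.atom_b,
        heavy_sites=spec.heavy_sites,
        heavy_f=spec.heavy_f,
        heavy_b=spec.atom_b,
        seed=spec.structure_seed,
    )
    hkl, f_protein = structure_factors(protein, spec.cell, sym, d_min=spec.d_min)
    if heavy:
        _, f_heavy = structure_factors(heavy, spec.cell, sym, hkl=hkl)
    else:
        f_heavy = np.zeros(len(hkl), dtype=complex)
    d = resolution(hkl, spec.cell)
    a_ref = float(max(spec.cell.lengths))
    # calibrate |F|^2 to detector counts: pool-mean protein intensity ==
    # mean_counts, so counting noise lands in the serial-data <I/sigma> regime
    counts_per_f2 = spec.mean_counts / float(np.mean(np.abs(f_protein) ** 2))

    n_total = spec.n_native + spec.n_derivative
    if n_total == 0:
        raise ValueError("pool must contain at least one crystal")
    rng = np.random.default_rng(spec.seed)
    labels = np.array(["native"] * spec.n_native + ["derivative"] * spec.n_derivative)
    rng.shuffle(labels)

    width = max(3, len(str(n_total - 1)))
    lengths = spec.cell.lengths
    is_tetra_like = abs(lengths[0] - lengths[1]) < 1e-9

    frames = []
    cells: dict[str, UnitCell] = {}
    truth_rows = []
    for idx in range(n_total):
        ds = f"xtal_{idx:0{width}d}"
        label = labels[idx]
        if label == "native":
            mu, sd = spec.occupancy_native
            offset = spec.cell_offset_native
        else:
            mu, sd = spec.occupancy_derivative
            offset = spec.cell_offset_derivative
        occ = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
        # per-axis fractional jitter around the sub-population centre
        if is_tetra_like:
            d_ab = rng.normal(offset, spec.cell_jitter_sd)
            d_c = rng.normal(offset, spec.cell_jitter_sd)
            deltas = np.array([d_ab, d_ab, d_c])
        else:
            deltas = rng.normal(offset, spec.cell_jitter_sd, size=3)
        eps = float(np.sqrt(np.mean(deltas**2)))
        new_lengths = lengths * (1.0 + deltas)
        cell_c = UnitCell(*new_lengths, spec.cell.alpha, spec.cell.beta, spec.cell.gamma)
        scale = float(rng.lognormal(0.0, spec.scale_sd))

        i_true = counts_per_f2 * np.abs(f_protein + occ * f_heavy) ** 2
        i_pert = apply_non_isomorphism(i_true, eps, d, a_ref, rng)

        seen = rng.random(len(hkl)) < spec.coverage_fraction
        seen_idx = np.flatnonzero(seen)
        if len(seen_idx) == 0:
            continue
        mult = 1 + rng.poisson(spec.mean_multiplicity - 1.0, size=len(seen_idx))
        obs_idx = np.repeat(seen_idx, mult)
        i_scaled = scale * i_pert[obs_idx]
        if spec.counting_noise:
            var = np.maximum(i_scaled, 0.0) + spec.noise_floor
        else:
            var = np.full(len(obs_idx), spec.noise_floor)
        sigma = np.sqrt(var)
        i_obs = i_scaled + rng.standard_normal(len(obs_idx)) * sigma

        frames.append(
            pd.DataFrame(
                {
                    "dataset_id": ds,
                    "h": hkl[obs_idx, 0],
                    "k": hkl[obs_idx, 1],
                    "l": hkl[obs_idx, 2],
                    "intensity": i_obs,
                    "sigma": sigma,
                }
            )
        )
        cells[ds] = cell_c
        truth_rows.append(
            {
                "dataset_id": ds,
                "label": label,
                "occupancy": occ,
                "epsilon": eps,
                "scale": scale,
                "n_obs": len(obs_idx),
            }
        )

    pool = ObservationTable(pd.concat(frames, ignore_index=True), cells, sym)
    truth = PoolTruth(
        table=pd.DataFrame(truth_rows),
        heavy_positions=np.array([a.position for a in heavy]) if heavy else np.empty((0, 3)),
        spec=spec,
    )
    return pool, truth


def write_simulated_pool(spec: PoolSpec, directory, fmt: str = "internal"):
    """Simulate and write a pool plus its truth.json; returns (pool, truth, paths)."""
    pool, truth = simulate_pool(spec)
    directory = Path(directory)
    paths = write_pool(pool, directory, fmt=fmt)
    truth.to_json(directory / "truth.json")
    return pool, truth, paths
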