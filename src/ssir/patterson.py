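"""Isomorphous-difference statistics and difference Patterson maps.

A desk-scale surrogate for downstream phasing success: with a correct
native/derivative split, the squared isomorphous amplitude differences
(dF)^2 Fourier-transform into a Patterson map whose non-origin peaks sit at
the interatomic vectors between heavy-atom sites.  Peak recovery against the
simulator's known sites stands in for substructure determination, which this
package deliberately does not perform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import UnitCell
from .iso import _r_between
from .merging import MergedGroup
from .symmetry import SymmetrySetting

__all__ = [
    "DifferenceSet",
    "PattersonMap",
    "difference_set",
    "difference_patterson",
    "find_peaks",
    "match_vectors",
]

MIN_COMMON_DIFF = 30


@dataclass
class DifferenceSet:
    """Per-reflection isomorphous amplitude differences dF = F_deriv - F_nat."""

    hkl: np.ndarray
    delta_f: np.ndarray
    sigma_delta_f: np.ndarray
    d: np.ndarray
    scale: float              # least-squares intensity scale of B onto A
    mean_abs_df_over_f: float

    def __len__(self) -> int:
        return len(self.hkl)


@dataclass
class PattersonMap:
    """Difference Patterson on a fractional grid over the unit cell."""

    values: np.ndarray        # (na, nb, nc), normalized by reflection count
    cell: UnitCell

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def fractional_coords(self) -> np.ndarray:
        na, nb, nc = self.values.shape
        fx = np.arange(na) / na
        fy = np.arange(nb) / nb
        fz = np.arange(nc) / nc
        return fx, fy, fz


def _match_common(a: MergedGroup, b: MergedGroup):
    enc = lambda hkl: (hkl[:, 0].astype(np.int64) * (1 << 21) + hkl[:, 1]) * (1 << 21) + hkl[:, 2]
    ka, kb = enc(a.hkl), enc(b.hkl)
    _, ia, ib = np.intersect1d(ka, kb, return_indices=True)
    return ia, ib


def difference_set(
    native: MergedGroup,
    derivative: MergedGroup,
    min_common: int = MIN_COMMON_DIFF,
    scaling: str = "lsq",
) -> DifferenceSet:
    """Isomorphous differences on reflections common to both groups.

    The derivative is scaled onto the native on intensities — ``lsq`` is the
    least-squares fit, ``symmetric`` the norm ratio sqrt(sum I_n^2/sum I_d^2)
    (exactly reciprocal under swapping the inputs).  Amplitudes are
    sqrt(max(I, 0)); sigma(dF) is propagated linearly (sigma_F = sigma_I / 2F
    for F > 0).
    """
    ia, ib = _match_common(native, derivative)
    if len(ia) < min_common:
        raise ValueError(f"only {len(ia)} common reflections (< {min_common})")
    i_n = native.intensity[ia]
    i_d = derivative.intensity[ib]
    denom = float(np.sum(i_d * i_d))
    if denom <= 0:
        raise ValueError("derivative intensities are degenerate")
    if scaling == "lsq":
        k = float(np.sum(i_n * i_d) / denom)
    elif scaling == "symmetric":
        k = float(np.sqrt(np.sum(i_n * i_n) / denom))
    else:
        raise ValueError("scaling must be 'lsq' or 'symmetric'")
    i_d = k * i_d
    s_n = native.sigma[ia]
    s_d = k * derivative.sigma[ib]

    f_n = np.sqrt(np.maximum(i_n, 0.0))
    f_d = np.sqrt(np.maximum(i_d, 0.0))
    with np.errstate(divide="ignore"):
        sf_n = np.where(f_n > 0, s_n / (2.0 * np.maximum(f_n, 1e-300)), np.sqrt(s_n))
        sf_d = np.where(f_d > 0, s_d / (2.0 * np.maximum(f_d, 1e-300)), np.sqrt(s_d))
    delta = f_d - f_n
    sigma_delta = np.sqrt(sf_n**2 + sf_d**2)
    mean_f = float(np.mean(0.5 * (f_n + f_d)))
    summary = float(np.mean(np.abs(delta)) / mean_f) if mean_f > 0 else np.nan
    cell = native.cell
    from .cells import resolution

    return DifferenceSet(
        hkl=native.hkl[ia],
        delta_f=delta,
        sigma_delta_f=sigma_delta,
        d=resolution(native.hkl[ia], cell),
        scale=k,
        mean_abs_df_over_f=summary,
    )


def difference_patterson(
    ds: DifferenceSet,
    cell: UnitCell,
    grid_step: float = None,
    d_min: float = None,
) -> PattersonMap:
    """P(u) = sum_h dF^2 cos(2 pi h.u) / N on a fractional grid.

    ``grid_step`` is in Angstrom (default d_min/3).  A grid coarser than
    d_min/2 triggers a warning.  The map is centrosymmetric by construction
    and maximal at the origin.
    """
    if len(ds) == 0:
        raise ValueError("empty difference set")
    if d_min is None:
        d_min = float(ds.d.min())
    if grid_step is None:
        grid_step = d_min / 3.0
    if grid_step > d_min / 2.0:
        warnings.warn("Patterson grid coarser than d_min/2; peaks may alias",
                      stacklevel=2)
    n = np.maximum(np.ceil(cell.lengths / grid_step).astype(int), 4)
    fx = np.arange(n[0]) / n[0]
    fy = np.arange(n[1]) / n[1]
    fz = np.arange(n[2]) / n[2]
    coeff = ds.delta_f.astype(np.float64) ** 2
    values = np.zeros(tuple(n))
    # chunked direct cosine summation (small problems; transparent and exact)
    chunk = max(1, int(2e7 // values.size))
    hkl = ds.hkl
    for start in range(0, len(hkl), chunk):
        hh = hkl[start:start + chunk]
        cc = coeff[start:start + chunk]
        phase = 2.0 * np.pi * (
            hh[:, 0, None, None, None] * fx[None, :, None, None]
            + hh[:, 1, None, None, None] * fy[None, None, :, None]
            + hh[:, 2, None, None, None] * fz[None, None, None, :]
        )
        values += np.tensordot(cc, np.cos(phase), axes=(0, 0))
    values /= len(hkl)
    return PattersonMap(values=values, cell=cell)


def find_peaks(
    pmap: PattersonMap,
    n_peaks: int = 10,
    origin_exclusion_radius: float = None,
) -> pd.DataFrame:
    """Ranked non-origin local maxima; heights in map sigmas above the mean.

    ``origin_exclusion_radius`` is in Angstrom (default 0.1 x the shortest
    cell edge); positions are nearest-grid fractional coordinates.
    """
    v = pmap.values
    if not np.all(np.isfinite(v)):
        raise ValueError("map contains non-finite values")
    mean, sd = float(v.mean()), float(v.std())
    if sd == 0:
        return pd.DataFrame(columns=["rank", "x", "y", "z", "height_sigma"])
    if origin_exclusion_radius is None:
        origin_exclusion_radius = 0.1 * float(min(pmap.cell.lengths))

    local_max = np.ones_like(v, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            local_max &= v >= np.roll(v, shift, axis=axis)

    na, nb, nc = v.shape
    fx = np.arange(na) / na
    fy = np.arange(nb) / nb
    fz = np.arange(nc) / nc
    gx, gy, gz = np.meshgrid(fx, fy, fz, indexing="ij")
    frac = np.stack([gx, gy, gz], axis=-1)
    # minimum-image Cartesian distance to the origin
    mi = np.where(frac > 0.5, frac - 1.0, frac)
    ortho = pmap.cell.orthogonalization_matrix()
    cart = mi @ ortho.T
    dist = np.sqrt((cart**2).sum(axis=-1))
    candidate = local_max & (dist > origin_exclusion_radius)

    idx = np.argwhere(candidate)
    heights = (v[candidate] - mean) / sd
    order = np.argsort(-heights, kind="stable")[:n_peaks]
    rows = []
    for rank, o in enumerate(order, start=1):
        i, j, k = idx[o]
        rows.append({
            "rank": rank,
            "x": fx[i],
            "y": fy[j],
            "z": fz[k],
            "height_sigma": float(heights[o]),
        })
    return pd.DataFrame(rows)


def _difference_vectors(heavy_positions: np.ndarray, sym: SymmetrySetting = None) -> np.ndarray:
    """All interatomic difference vectors between symmetry copies of the sites
    (mod 1), excluding the origin-coincident self vectors."""
    pos = np.asarray(heavy_positions, dtype=float) % 1.0
    if sym is not None:
        expanded = []
        for rot, trans in sym.spacegroup_operators():
            expanded.append((pos @ rot.T + trans) % 1.0)
        pos = np.vstack(expanded)
    diffs = (pos[:, None, :] - pos[None, :, :]).reshape(-1, 3) % 1.0
    keep = ~np.all(np.isclose(diffs, 0.0) | np.isclose(diffs, 1.0), axis=1)
    return diffs[keep]


def match_vectors(
    peaks: pd.DataFrame,
    heavy_positions: np.ndarray,
    cell: UnitCell,
    sym: SymmetrySetting = None,
    tolerance: float = 1.0,
) -> dict:
    """Compare peak positions against the true heavy-atom difference vectors.

    ``tolerance`` is a Cartesian distance in Angstrom (minimum image, both
    signs of each vector).  Returns matched fraction, per-peak flags and the
    rms offset of the matched peaks.
    """
    if len(peaks) == 0:
        return {"matched_fraction": 0.0, "rms_offset": np.nan, "matched": []}
    targets = _difference_vectors(heavy_positions, sym)
    if len(targets) == 0:
        return {"matched_fraction": 0.0, "rms_offset": np.nan,
                "matched": [False] * len(peaks)}
    targets = np.vstack([targets, (-targets) % 1.0])
    ortho = cell.orthogonalization_matrix()
    matched = []
    offsets = []
    for _, row in peaks.iterrows():
        p = np.array([row["x"], row["y"], row["z"]])
        delta = (targets - p + 0.5) % 1.0 - 0.5
        dist = np.sqrt(((delta @ ortho.T) ** 2).sum(axis=1))
        dmin = float(dist.min())
        ok = dmin <= tolerance
        matched.append(bool(ok))
        if ok:
            offsets.append(dmin)
    frac = float(np.mean(matched))
    rms = float(np.sqrt(np.mean(np.square(offsets)))) if offsets else np.nan
    return {"matched_fraction": frac, "rms_offset": rms, "matched": matched}
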