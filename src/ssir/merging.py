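"""Scaling, merging and data-quality statistics for groups of partial datasets.

The statistics follow the community conventions: R_merge, the
multiplicity-corrected R_meas (x sqrt(n/(n-1)) per reflection), the
precision-indicating R_pim (x sqrt(1/(n-1))), CC1/2 from random half-set
merges, <I/sigma(I)> of the inverse-variance merged intensities,
completeness against the enumerated unique set, and multiplicity.

Statistics that cannot be computed (e.g. no multiply-observed reflection)
are reported as None — never as 0 — so downstream scoring can penalize them
explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cells import UnitCell, resolution
from .io import ObservationTable
from .symmetry import SymmetrySetting, enumerate_unique

log = logging.getLogger("ssir")

__all__ = [
    "ShellScheme",
    "MergedGroup",
    "MergeStats",
    "choose_reference",
    "scale_to_reference",
    "apply_scales",
    "merge",
    "compute_stats",
    "cc_half",
    "inner_shell_rmeas",
    "cell_range_report",
    "theoretical_unique",
]

MIN_COMMON_SCALE = 20  # default minimum shared unique reflections for scaling


@dataclass(frozen=True)
class ShellScheme:
    """Resolution shells of equal reciprocal volume.

    ``boundaries`` are n_shells+1 d-spacing cut points, strictly decreasing;
    shell 0 is the lowest-resolution ("inner") shell.
    """

    boundaries: np.ndarray

    @classmethod
    def equal_volume(cls, d_min: float, d_max: float, n_shells: int = 10) -> "ShellScheme":
        if d_min <= 0 or d_max < d_min:
            raise ValueError("need 0 < d_min <= d_max")
        if n_shells < 1:
            raise ValueError("need at least one shell")
        if d_max - d_min < 1e-9:  # degenerate range (e.g. one reflection)
            d_min, d_max = 0.999 * d_min, 1.001 * d_max
        s3 = np.linspace(d_max ** -3, d_min ** -3, n_shells + 1)
        return cls(boundaries=s3 ** (-1.0 / 3.0))

    @property
    def n_shells(self) -> int:
        return len(self.boundaries) - 1

    def shell_of(self, d: np.ndarray) -> np.ndarray:
        """Shell index (0 = inner) per d-spacing; values clipped into range."""
        idx = np.searchsorted(-self.boundaries, -np.asarray(d, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.n_shells - 1)


@dataclass
class MergedGroup:
    """Unique-reflection intensities of one group of partial datasets."""

    hkl: np.ndarray           # (N,3) ASU indices
    intensity: np.ndarray     # inverse-variance weighted means
    sigma: np.ndarray         # (sum 1/sigma_i^2)^-1/2
    n_obs: np.ndarray         # observations per unique reflection
    member_ids: list[str]
    cell: UnitCell            # average over members
    cell_min: np.ndarray = field(default=None)
    cell_max: np.ndarray = field(default=None)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def total_observations(self) -> int:
        return int(self.n_obs.sum())

    def d_spacings(self) -> np.ndarray:
        return resolution(self.hkl, self.cell)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h": self.hkl[:, 0],
                "k": self.hkl[:, 1],
                "l": self.hkl[:, 2],
                "intensity": self.intensity,
                "sigma": self.sigma,
                "n_obs": self.n_obs,
            }
        )


@dataclass
class MergeStats:
    """Overall merging statistics plus a per-shell breakdown.

    Fractions are unitless (completeness in [0,1]); undefined values are None.
    """

    r_merge: Optional[float]
    r_meas: Optional[float]
    r_pim: Optional[float]
    cc_half: Optional[float]
    i_over_sig: Optional[float]
    completeness: Optional[float]
    multiplicity: Optional[float]
    n_obs: int
    n_unique: int
    per_shell: pd.DataFrame = None

    def to_row(self) -> dict:
        return {
            "r_merge": self.r_merge,
            "r_meas": self.r_meas,
            "r_pim": self.r_pim,
            "cc_half": self.cc_half,
            "i_over_sig": self.i_over_sig,
            "completeness": self.completeness,
            "multiplicity": self.multiplicity,
            "n_obs": self.n_obs,
            "n_unique": self.n_unique,
        }


# ---------------------------------------------------------------------------
# helpers


def _uid_index(pool: ObservationTable):
    """Map every observation to a dense unique-reflection index.

    Returns (uid per obs, unique (U,3) hkl array).
    """
    asu = pool.asu_hkl()
    uniq, uid = np.unique(asu, axis=0, return_inverse=True)
    return uid.ravel(), uniq


def _dataset_indices(pool: ObservationTable):
    ids = pool.dataset_ids
    lookup = {d: i for i, d in enumerate(ids)}
    did = pool.df["dataset_id"].map(lookup).to_numpy()
    return did, ids


def pool_d_range(pool: ObservationTable) -> tuple[float, float]:
    d = resolution(pool.asu_hkl(), pool.mean_cell())
    return float(d.min()), float(d.max())


def theoretical_unique(pool: ObservationTable, d_range: tuple[float, float] = None) -> np.ndarray:
    """Enumerated unique set over the pool's resolution range (completeness denominator)."""
    if d_range is None:
        d_range = pool_d_range(pool)
    return enumerate_unique(pool.mean_cell(), pool.symmetry, d_range[0], d_range[1])


# ---------------------------------------------------------------------------
# operations


def choose_reference(pool: ObservationTable) -> str:
    """Dataset with the highest unmerged mean I/sigma (ties: lexicographic id)."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    snr = pool.df["intensity"] / pool.df["sigma"]
    means = snr.groupby(pool.df["dataset_id"]).mean()
    best = means.max()
    candidates = sorted(means.index[means >= best - 1e-12])
    return str(candidates[0])


def _lsq_scale(i_ref, i_d, w) -> float:
    """k minimizing sum w (I_ref - k I_d)^2."""
    denom = float(np.sum(w * i_d * i_d))
    if denom <= 0:
        return np.nan
    return float(np.sum(w * i_ref * i_d) / denom)


def scale_to_reference(
    pool: ObservationTable,
    reference: str = None,
    min_common: int = MIN_COMMON_SCALE,
) -> dict[str, float]:
    """Per-dataset linear scale factors onto a reference dataset.

    Each dataset is first merged internally to unique reflections; the scale
    minimizes the inverse-variance weighted squared difference on reflections
    shared with the reference.  Datasets without ``min_common`` shared
    reflections are scaled transitively through the overlap graph
    (breadth-first from the reference); unreachable datasets are flagged with
    a NaN scale and a logged warning.
    """
    if reference is None:
        reference = choose_reference(pool)
    uid, _ = _uid_index(pool)
    did, ids = _dataset_indices(pool)
    if reference not in ids:
        raise ValueError(f"reference {reference!r} not in pool")
    n_ds = len(ids)
    u_max = uid.max() + 1

    # per-dataset internal merge (inverse-variance) on the shared uid space
    w_obs = 1.0 / pool.df["sigma"].to_numpy() ** 2
    i_obs = pool.df["intensity"].to_numpy()
    key = did.astype(np.int64) * u_max + uid
    order = np.argsort(key, kind="stable")
    key_s, uniq_idx = np.unique(key[order], return_index=True)
    sw = np.add.reduceat(w_obs[order], uniq_idx)
    swi = np.add.reduceat((w_obs * i_obs)[order], uniq_idx)
    ds_of = (key_s // u_max).astype(int)
    uid_of = (key_s % u_max).astype(int)
    merged_i = swi / sw
    merged_w = sw

    per_ds = [None] * n_ds
    for d in range(n_ds):
        sel = ds_of == d
        per_ds[d] = (uid_of[sel], merged_i[sel], merged_w[sel])

    scales: dict[str, float] = {ids[i]: np.nan for i in range(n_ds)}
    ref_idx = ids.index(reference)
    scales[reference] = 1.0

    def common_scale(d_target, base_uid, base_i, base_w):
        tu, ti, tw = per_ds[d_target]
        common, ia, ib = np.intersect1d(base_uid, tu, return_indices=True)
        if len(common) < min_common:
            return None
        w = 1.0 / (1.0 / base_w[ia] + 1.0 / tw[ib])
        return _lsq_scale(base_i[ia], ti[ib], w)

    # BFS through the overlap graph starting at the reference
    frontier = [ref_idx]
    done = {ref_idx}
    while frontier:
        nxt = []
        for d in range(n_ds):
            if d in done:
                continue
            for b in frontier:
                bu, bi, bw = per_ds[b]
                k_base = scales[ids[b]]
                k = common_scale(d, bu, k_base * bi, bw / k_base**2)
                if k is not None and k > 0:
                    scales[ids[d]] = k
                    nxt.append(d)
                    done.add(d)
                    break
        if not nxt:
            break
        frontier = nxt

    unscalable = [i for i, v in scales.items() if not np.isfinite(v)]
    if unscalable:
        log.warning("unscalable datasets (fewer than %d common reflections on any path): %s",
                    min_common, ", ".join(unscalable))
    return scales


def apply_scales(pool: ObservationTable, scales: dict[str, float]) -> ObservationTable:
    """Multiply intensities and sigmas by each dataset's scale; drop unscalable ones."""
    good = {d for d, k in scales.items() if np.isfinite(k) and k > 0}
    sub = pool.subset(good)
    k = sub.df["dataset_id"].map(scales).to_numpy()
    df = sub.df.copy()
    df["intensity"] = df["intensity"] * k
    df["sigma"] = df["sigma"] * k
    return ObservationTable(df, sub.cells, sub.symmetry)


def merge(pool: ObservationTable, member_ids: Sequence[str] = None,
          sym: SymmetrySetting = None) -> MergedGroup:
    """Inverse-variance merge of (a subset of) a pool to unique reflections.

    I = sum(I_i/sigma_i^2)/sum(1/sigma_i^2); sigma = (sum 1/sigma_i^2)^-1/2.
    """
    if member_ids is not None:
        member_ids = list(member_ids)
        if not member_ids:
            raise ValueError("empty member set")
        pool = pool.subset(member_ids)
    else:
        member_ids = pool.dataset_ids
    if len(pool) == 0:
        raise ValueError("no observations to merge")
    uid, uniq = _uid_index(pool)
    w = 1.0 / pool.df["sigma"].to_numpy() ** 2
    i = pool.df["intensity"].to_numpy()
    U = len(uniq)
    sw = np.bincount(uid, weights=w, minlength=U)
    swi = np.bincount(uid, weights=w * i, minlength=U)
    n = np.bincount(uid, minlength=U)
    cells = np.array([pool.cells[d].as_tuple() for d in sorted(member_ids)])
    return MergedGroup(
        hkl=uniq,
        intensity=swi / sw,
        sigma=sw ** -0.5,
        n_obs=n,
        member_ids=sorted(member_ids),
        cell=UnitCell(*cells.mean(axis=0)),
        cell_min=cells.min(axis=0),
        cell_max=cells.max(axis=0),
    )


def _r_factors(i_obs, uid, n, sum_i, shell_mask_uid=None):
    """R_merge/R_meas/R_pim from observations and per-uid counts/sums."""
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_i = np.where(n > 0, sum_i / np.maximum(n, 1), 0.0)
    dev = np.abs(i_obs - mean_i[uid])
    dev_uid = np.bincount(uid, weights=dev, minlength=len(n))
    multi = n >= 2
    if shell_mask_uid is not None:
        multi = multi & shell_mask_uid
    if not multi.any():
        return None, None, None
    nn = n[multi].astype(float)
    devm = dev_uid[multi]
    denom = float(sum_i[multi].sum())
    if denom <= 0:
        return None, None, None
    r_merge = float(devm.sum() / denom)
    r_meas = float((devm * np.sqrt(nn / (nn - 1))).sum() / denom)
    r_pim = float((devm * np.sqrt(1.0 / (nn - 1))).sum() / denom)
    return r_merge, r_meas, r_pim


def cc_half(
    group: MergedGroup,
    pool: ObservationTable,
    seed: int = 0,
    n_splits: int = 20,
) -> Optional[float]:
    """CC1/2 by repeated seeded random half-splits of each reflection's observations.

    For each split, observations of every multiply-observed reflection are
    randomly divided into two halves (sizes n//2 and n-n//2); the Pearson
    correlation of the two half-set mean vectors is averaged over splits.
    Returns None when fewer than 3 reflections have >= 2 observations.
    """
    sub = pool.subset(group.member_ids)
    uid, uniq = _uid_index(sub)
    i_obs = sub.df["intensity"].to_numpy()
    U = len(uniq)
    n = np.bincount(uid, minlength=U)
    if int((n >= 2).sum()) < 3:
        return None
    rng = np.random.default_rng(seed)
    # positions of observations sorted by uid, for within-reflection ranking
    base_order = np.argsort(uid, kind="stable")
    starts = np.concatenate([[0], np.cumsum(n)])[:-1]
    start_per_obs = np.repeat(starts, n)
    ccs = []
    half_a = n // 2
    for _ in range(n_splits):
        r = rng.random(len(uid))
        order = np.lexsort((r, uid))
        rank = np.empty(len(uid), dtype=np.int64)
        rank[order] = np.arange(len(uid)) - start_per_obs
        in_a = rank < half_a[uid]
        na = np.bincount(uid[in_a], minlength=U)
        sa = np.bincount(uid[in_a], weights=i_obs[in_a], minlength=U)
        nb = n - na
        sb = np.bincount(uid, weights=i_obs, minlength=U) - sa
        valid = (na >= 1) & (nb >= 1)
        if valid.sum() < 3:
            continue
        ma, mb = sa[valid] / na[valid], sb[valid] / nb[valid]
        if np.std(ma) == 0 or np.std(mb) == 0:
            ccs.append(1.0 if np.allclose(ma, mb) else 0.0)
            continue
        ccs.append(float(np.corrcoef(ma, mb)[0, 1]))
    if not ccs:
        return None
    return float(np.mean(ccs))


def compute_stats(
    group: MergedGroup,
    pool: ObservationTable,
    shells: ShellScheme = None,
    reference_unique: np.ndarray = None,
    cc_seed: int = 0,
    cc_splits: int = 20,
) -> MergeStats:
    """Table-style merging statistics for one merged group.

    ``reference_unique`` (the enumerated unique set for the completeness
    denominator) defaults to the whole pool's resolution range so that groups
    of the same pool are directly comparable.
    """
    sub = pool.subset(group.member_ids)
    uid, uniq = _uid_index(sub)
    i_obs = sub.df["intensity"].to_numpy()
    U = len(uniq)
    n = np.bincount(uid, minlength=U)
    sum_i = np.bincount(uid, weights=i_obs, minlength=U)

    d_pool_min, d_pool_max = pool_d_range(pool)
    if shells is None:
        shells = ShellScheme.equal_volume(d_pool_min, d_pool_max, 10)
    if reference_unique is None:
        reference_unique = theoretical_unique(pool)
    cell = pool.mean_cell()
    d_uid = resolution(uniq, cell)
    shell_uid = shells.shell_of(d_uid)
    d_ref = resolution(reference_unique, cell)
    shell_ref = shells.shell_of(d_ref)

    r_merge, r_meas, r_pim = _r_factors(i_obs, uid, n, sum_i)
    merged_i = group.intensity
    merged_sig = group.sigma
    # group and sub share the same unique ordering (np.unique is sorted)
    i_over_sig = float(np.mean(merged_i / merged_sig)) if U else None
    n_theory = len(reference_unique)
    completeness = float(U / n_theory) if n_theory else None
    multiplicity = float(n.sum() / U) if U else None
    cc = cc_half(group, pool, seed=cc_seed, n_splits=cc_splits)

    rows = []
    for s in range(shells.n_shells):
        in_shell = shell_uid == s
        nth = int((shell_ref == s).sum())
        nu = int(in_shell.sum())
        rm, rme, rp = _r_factors(i_obs, uid, n, sum_i, shell_mask_uid=in_shell)
        rows.append(
            {
                "shell": s,
                "d_max": shells.boundaries[s],
                "d_min": shells.boundaries[s + 1],
                "n_unique": nu,
                "n_obs": int(n[in_shell].sum()),
                "completeness": nu / nth if nth else np.nan,
                "multiplicity": float(n[in_shell].sum() / nu) if nu else np.nan,
                "i_over_sig": float(np.mean(merged_i[in_shell] / merged_sig[in_shell])) if nu else np.nan,
                "r_merge": np.nan if rm is None else rm,
                "r_meas": np.nan if rme is None else rme,
                "r_pim": np.nan if rp is None else rp,
            }
        )
    per_shell = pd.DataFrame(rows)
    return MergeStats(
        r_merge=r_merge,
        r_meas=r_meas,
        r_pim=r_pim,
        cc_half=cc,
        i_over_sig=i_over_sig,
        completeness=completeness,
        multiplicity=multiplicity,
        n_obs=int(n.sum()),
        n_unique=U,
        per_shell=per_shell,
    )


def inner_shell_rmeas(group: MergedGroup, pool: ObservationTable,
                      shells: ShellScheme = None) -> Optional[float]:
    """R_meas restricted to the lowest-resolution shell (None if undefined)."""
    sub = pool.subset(group.member_ids)
    uid, uniq = _uid_index(sub)
    i_obs = sub.df["intensity"].to_numpy()
    n = np.bincount(uid, minlength=len(uniq))
    sum_i = np.bincount(uid, weights=i_obs, minlength=len(uniq))
    if shells is None:
        d0, d1 = pool_d_range(pool)
        shells = ShellScheme.equal_volume(d0, d1, 10)
    d_uid = resolution(uniq, pool.mean_cell())
    in_inner = shells.shell_of(d_uid) == 0
    _, r_meas, _ = _r_factors(i_obs, uid, n, sum_i, shell_mask_uid=in_inner)
    return r_meas


def cell_range_report(group: MergedGroup) -> pd.DataFrame:
    """Per-axis (min, mean, max) of the member unit cells."""
    names = ["a", "b", "c", "alpha", "beta", "gamma"]
    return pd.DataFrame(
        {
            "axis": names,
            "min": group.cell_min,
            "mean": np.array(group.cell.as_tuple()),
            "max": group.cell_max,
        }
    )
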