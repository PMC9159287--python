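"""Genetic-algorithm partitioning of a pool into internally isomorphous groups.

The genome is a label vector assigning each partial dataset to one of K
groups.  Fitness is the mean over groups of

    (100 - 100*R_meas) w_R + <I/sig> w_Isig + 100*CC1/2 w_CC
    + 100*completeness w_C + multiplicity w_M

plus the ISO term of the maximal-ratio group pair (see :mod:`ssir.iso`).
Evolution is tournament selection, uniform crossover, per-gene mutation and
elitism, fully reproducible under an explicit seed.
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import merging
from ._kernels import dataset_aggregates, deviation_sums
from .cells import resolution
from .io import ObservationTable
from .iso import ISO_MIN_COMMON, RATIO_CAP, IsoReport, iso_ratio
from .merging import MergedGroup, ShellScheme, compute_stats
from .util import adjusted_rand_index

__all__ = [
    "FitnessWeights",
    "GAConfig",
    "Partition",
    "TrajectoryRecord",
    "PartitionEvaluator",
    "group_fitness",
    "partition_fitness",
    "evolve",
    "select_best_pair",
    "GroupingModel",
    "GroupingResults",
]

PENALTY = -1.0e6


@dataclass(frozen=True)
class FitnessWeights:
    """Non-negative weights of the compound fitness R + I + CC + C + M + ISO."""

    w_r: float = 1.0
    w_isig: float = 1.0
    w_cc: float = 1.0
    w_completeness: float = 1.0
    w_multiplicity: float = 1.0
    w_iso: float = 100.0

    def __post_init__(self) -> None:
        vals = (self.w_r, self.w_isig, self.w_cc, self.w_completeness,
                self.w_multiplicity, self.w_iso)
        if any(v < 0 for v in vals):
            raise ValueError("weights must be non-negative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one weight must be positive")


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters; the seed is mandatory for reproducible runs."""

    k: int = 4
    population_size: int = 100
    generations: int = 50
    tournament_size: int = 3
    crossover_prob: float = 0.8
    mutation_prob: Optional[float] = None  # default 1/n_datasets
    elitism_count: int = 2
    min_group_size: int = 2
    seed: int = 0
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    penalty: float = PENALTY
    iso_min_common: int = ISO_MIN_COMMON
    iso_ratio_cap: float = RATIO_CAP
    iso_ratio_direction: str = "inter_over_intra"  # or "intra_over_inter"
    iso_intra_mode: str = "dataset"  # or "merged": see PartitionEvaluator
    iso_symmetric: bool = False
    aggregate: str = "mean"  # or "sum" across groups
    cc_splits: int = 8       # CC1/2 half-splits inside the fitness (max 8)
    polish: bool = True      # final single-dataset hill-climb of the best partition

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least two groups")
        if self.population_size < 2 * max(self.elitism_count, 1):
            raise ValueError("population_size must be >= 2*elitism_count")
        if not 1 <= self.cc_splits <= 8:
            raise ValueError("cc_splits must be in 1..8")
        if self.iso_ratio_direction not in ("inter_over_intra", "intra_over_inter"):
            raise ValueError("unknown iso_ratio_direction")
        if self.iso_intra_mode not in ("dataset", "merged"):
            raise ValueError("iso_intra_mode must be 'dataset' or 'merged'")
        if self.aggregate not in ("mean", "sum"):
            raise ValueError("aggregate must be 'mean' or 'sum'")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown GAConfig keys: {sorted(unknown)}")
        if "weights" in d and isinstance(d["weights"], dict):
            wk = set(d["weights"]) - set(FitnessWeights.__dataclass_fields__)
            if wk:
                raise ValueError(f"unknown weight keys: {sorted(wk)}")
            d["weights"] = FitnessWeights(**d["weights"])
        return cls(**d)


@dataclass
class Partition:
    """Assignment of each dataset to one of K groups (labels are 0-based)."""

    labels: np.ndarray
    dataset_ids: list[str]
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels out of range")

    def members(self, group: int) -> list[str]:
        return [d for d, g in zip(self.dataset_ids, self.labels) if g == group]

    @property
    def one_based(self) -> np.ndarray:
        return self.labels + 1

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class TrajectoryRecord:
    generation: int
    best_fitness: float
    mean_fitness: float
    best_labels: list[int]
    iso: Optional[dict] = None
    truth_ari: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def group_fitness(stats, weights: FitnessWeights, penalty: float = PENALTY) -> float:
    """Merging-statistics part of the fitness for one group.

    ``stats`` is a MergeStats or any object with r_meas, i_over_sig, cc_half,
    completeness, multiplicity attributes (fractions in [0,1]; None =
    undefined).  A statistic is only required when its weight is positive;
    any required-but-undefined statistic yields the penalty value.
    """
    w = weights
    terms = [
        (w.w_r, None if stats.r_meas is None else (100.0 - 100.0 * stats.r_meas)),
        (w.w_isig, stats.i_over_sig),
        (w.w_cc, None if stats.cc_half is None else 100.0 * stats.cc_half),
        (w.w_completeness, None if stats.completeness is None else 100.0 * stats.completeness),
        (w.w_multiplicity, stats.multiplicity),
    ]
    total = 0.0
    for weight, value in terms:
        if weight == 0:
            continue
        if value is None:
            return penalty
        total += weight * value
    return total


class _GroupScore:
    """Cached per-group evaluation: fitness ingredients + merged vector."""

    __slots__ = ("fitness", "r_meas", "i_over_sig", "cc_half", "completeness",
                 "multiplicity", "inner_rmeas", "merged_i", "present", "n_obs")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


class PartitionEvaluator:
    """Fast, cached fitness evaluation of partitions of one (scaled) pool.

    All randomness (the CC1/2 half-assignments) is pre-drawn from the config
    seed, so evaluation is a pure function of the label vector: results are
    independent of evaluation order and safe to cache or parallelize.

    The R factor, <I/sigma>, completeness and multiplicity formulas are
    identical to :func:`ssir.merging.compute_stats`.  CC1/2 inside the
    fitness is estimated from ``cc_splits`` pre-drawn random half-splits of
    each group's member *datasets* (correlating the two half-pool merges),
    a cheap deterministic stand-in for the per-observation half-splits that
    :func:`ssir.merging.cc_half` uses for reporting.
    """

    def __init__(self, pool: ObservationTable, config: GAConfig,
                 shells: ShellScheme = None, cache_size: int = 4096,
                 share_from: "PartitionEvaluator" = None):
        self.pool = pool
        self.config = config
        self.dataset_ids = pool.dataset_ids
        self.n_datasets = len(self.dataset_ids)
        if share_from is not None and share_from.pool is pool:
            # reuse the expensive pool-level precomputations of another
            # evaluator on the same pool (e.g. a different K or weights)
            for attr in ("unique_hkl", "n_unique", "uid", "i_obs", "w_obs",
                         "ds_offsets", "shells", "inner_mask", "n_theory",
                         "m_n", "m_i", "m_w", "m_wi", "ds_inner_rmeas"):
                setattr(self, attr, getattr(share_from, attr))
        else:
            uid, uniq = merging._uid_index(pool)
            self.unique_hkl = uniq
            self.n_unique = len(uniq)
            lookup = {d: i for i, d in enumerate(self.dataset_ids)}
            did = pool.df["dataset_id"].map(lookup).to_numpy(dtype=np.int64)
            # sort observations by dataset so group evaluation touches only
            # the member slices
            order = np.argsort(did, kind="stable")
            self.uid = uid.astype(np.int64)[order]
            did = did[order]
            self.i_obs = pool.df["intensity"].to_numpy(dtype=np.float64)[order]
            self.w_obs = 1.0 / pool.df["sigma"].to_numpy(dtype=np.float64)[order] ** 2
            counts = np.bincount(did, minlength=self.n_datasets)
            self.ds_offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
            cell = pool.mean_cell()
            d_uid = resolution(uniq, cell)
            d_lo, d_hi = float(d_uid.min()), float(d_uid.max())
            if shells is None:
                shells = ShellScheme.equal_volume(d_lo, d_hi, 10)
            self.shells = shells
            self.inner_mask = self.shells.shell_of(d_uid) == 0
            self.n_theory = max(len(merging.theoretical_unique(pool, (d_lo, d_hi))), 1)
            self.m_n, self.m_i, self.m_w, self.m_wi = dataset_aggregates(
                self.uid, self.i_obs, self.w_obs, self.ds_offsets,
                self.n_datasets, self.n_unique,
            )
            # per-dataset inner-shell R_meas: the "individual average"
            # intra-dataset noise level the default ISO denominator uses
            self.ds_inner_rmeas = np.full(self.n_datasets, np.nan)
            for d in range(self.n_datasets):
                nd = self.m_n[d]
                nd_int = nd.astype(np.int64)
                with np.errstate(divide="ignore", invalid="ignore"):
                    mean_d = np.where(nd > 0, self.m_i[d] / np.maximum(nd, 1.0), 0.0)
                dev_d = deviation_sums(self.uid, self.i_obs, self.ds_offsets,
                                       np.array([d], dtype=np.int64),
                                       nd_int, mean_d, self.n_unique)
                r = self._rfactor(dev_d, nd_int, self.m_i[d],
                                  (nd_int >= 2) & self.inner_mask)
                if r is not None:
                    self.ds_inner_rmeas[d] = r
        ss = np.random.SeedSequence(config.seed)
        _, ss_cc = ss.spawn(2)
        rng = np.random.default_rng(ss_cc)
        self.ds_half = rng.integers(0, 2, size=(config.cc_splits, self.n_datasets)
                                    ).astype(np.float64)
        self._group_cache: OrderedDict = OrderedDict()
        self._pair_cache: dict = {}
        self._cache_size = cache_size
        self.n_group_evals = 0

    # -- group level --------------------------------------------------------

    def group_score(self, members: frozenset) -> _GroupScore:
        hit = self._group_cache.get(members)
        if hit is not None:
            self._group_cache.move_to_end(members)
            return hit
        score = self._evaluate_group(members)
        self._group_cache[members] = score
        if len(self._group_cache) > self._cache_size:
            self._group_cache.popitem(last=False)
        return score

    def _evaluate_group(self, members: frozenset) -> _GroupScore:
        self.n_group_evals += 1
        cfg = self.config
        idx = sorted(self.dataset_ids.index(d) if isinstance(d, str) else int(d)
                     for d in members)
        members_arr = np.asarray(idx, dtype=np.int64)
        n = self.m_n[idx].sum(axis=0)
        s_i = self.m_i[idx].sum(axis=0)
        s_w = self.m_w[idx].sum(axis=0)
        s_wi = self.m_wi[idx].sum(axis=0)
        present = n > 0
        n_uniq = int(present.sum())
        n_obs = int(round(n.sum()))
        if n_uniq == 0:
            return _GroupScore(fitness=cfg.penalty, r_meas=None, i_over_sig=None,
                               cc_half=None, completeness=None, multiplicity=None,
                               inner_rmeas=None, merged_i=None, present=present, n_obs=0)

        with np.errstate(divide="ignore", invalid="ignore"):
            mean_i = np.where(present, s_i / np.maximum(n, 1.0), 0.0)
        n_int = n.astype(np.int64)
        dev = deviation_sums(self.uid, self.i_obs, self.ds_offsets, members_arr,
                             n_int, mean_i, self.n_unique)
        multi = n_int >= 2
        r_meas = self._rfactor(dev, n_int, s_i, multi)
        inner_rmeas = self._rfactor(dev, n_int, s_i, multi & self.inner_mask)
        with np.errstate(divide="ignore", invalid="ignore"):
            merged = np.where(present, s_wi / np.maximum(s_w, 1e-300), 0.0)
        i_over_sig = float(np.mean((merged * np.sqrt(s_w))[present]))
        completeness = n_uniq / self.n_theory
        multiplicity = n_obs / n_uniq
        cc = self._cc_half(idx, n, s_i)
        stats = _GroupScore(
            fitness=0.0, r_meas=r_meas, i_over_sig=i_over_sig, cc_half=cc,
            completeness=completeness, multiplicity=multiplicity,
            inner_rmeas=inner_rmeas, merged_i=merged.astype(np.float32),
            present=present, n_obs=n_obs,
        )
        stats.fitness = group_fitness(stats, cfg.weights, cfg.penalty)
        return stats

    @staticmethod
    def _rfactor(dev, n, s_i, mask):
        if not mask.any():
            return None
        nn = n[mask].astype(np.float64)
        denom = float(s_i[mask].sum())
        if denom <= 0:
            return None
        return float((dev[mask] * np.sqrt(nn / (nn - 1.0))).sum() / denom)

    def _cc_half(self, idx, n, s_i) -> Optional[float]:
        # half-assignments of the member datasets, all splits at once
        w = self.ds_half[:, idx]                       # (S, m)
        a_n = w @ self.m_n[idx]                        # (S, U)
        a_i = w @ self.m_i[idx]
        ccs = []
        for s in range(self.config.cc_splits):
            na = a_n[s]
            nb = n - na
            valid = (na >= 1) & (nb >= 1)
            if int(valid.sum()) < 3:
                continue
            ma = a_i[s][valid] / na[valid]
            mb = (s_i[valid] - a_i[s][valid]) / nb[valid]
            ma = ma - ma.mean()
            mb = mb - mb.mean()
            denom = np.sqrt((ma @ ma) * (mb @ mb))
            if denom == 0:
                ccs.append(1.0 if np.allclose(ma, mb) else 0.0)
                continue
            ccs.append(float((ma @ mb) / denom))
        return float(np.mean(ccs)) if ccs else None

    # -- pair level ----------------------------------------------------------

    def pair_iso(self, members_a: frozenset, members_b: frozenset) -> IsoReport:
        # canonical direction: the lexicographically smaller member set is the
        # scaling reference, so the (slightly asymmetric) inter-group R is a
        # pure function of the unordered pair regardless of evaluation order
        members_a, members_b = sorted((members_a, members_b),
                                      key=lambda s: tuple(sorted(s)))
        key = (members_a, members_b)
        hit = self._pair_cache.get(key)
        if hit is not None:
            return hit
        cfg = self.config
        a, b = self.group_score(members_a), self.group_score(members_b)
        report = IsoReport(None, None, None, 0)
        if a.merged_i is not None and b.merged_i is not None:
            common = a.present & b.present
            n_common = int(common.sum())
            report.n_common = n_common
            if n_common >= cfg.iso_min_common:
                i_a = a.merged_i[common].astype(np.float64)
                i_b = b.merged_i[common].astype(np.float64)
                from .iso import _r_between

                r_int = _r_between(i_a, i_b, symmetric=cfg.iso_symmetric)
                if cfg.iso_intra_mode == "dataset":
                    vals = self.ds_inner_rmeas[sorted(members_a | members_b)]
                    vals = vals[np.isfinite(vals)]
                    r_intra = float(vals.mean()) if len(vals) else None
                else:
                    r_intra = (None if a.inner_rmeas is None or b.inner_rmeas is None
                               else 0.5 * (a.inner_rmeas + b.inner_rmeas))
                if cfg.iso_ratio_direction == "intra_over_inter" and r_int is not None:
                    ratio, capped = iso_ratio(r_intra, r_int, cfg.iso_ratio_cap)
                else:
                    ratio, capped = iso_ratio(r_int, r_intra, cfg.iso_ratio_cap)
                report = IsoReport(r_int, r_intra, ratio, n_common, capped)
        self._pair_cache[key] = report
        return report

    # -- partition level -----------------------------------------------------

    def groups_of(self, labels: np.ndarray) -> list[frozenset]:
        labels = np.asarray(labels)
        return [frozenset(int(i) for i in np.flatnonzero(labels == g))
                for g in range(self.config.k)]

    def best_pair(self, labels: np.ndarray) -> tuple[Optional[tuple[int, int]], Optional[IsoReport]]:
        """Unordered group pair with maximal ISO ratio (ties: smallest indices)."""
        groups = self.groups_of(labels)
        best = None
        best_pair = None
        for i in range(self.config.k):
            for j in range(i + 1, self.config.k):
                if not groups[i] or not groups[j]:
                    continue
                rep = self.pair_iso(groups[i], groups[j])
                if rep.ratio is None:
                    continue
                if best is None or rep.ratio > best.ratio + 1e-15:
                    best, best_pair = rep, (i, j)
        if best is not None:
            best = IsoReport(best.r_inter, best.r_intra_avg, best.ratio,
                             best.n_common, best.capped, pair=best_pair)
        return best_pair, best

    def partition_fitness(self, labels: np.ndarray) -> float:
        return self.partition_details(labels)[0]

    def partition_details(self, labels: np.ndarray):
        """(fitness, best-pair IsoReport or None) for one label vector."""
        cfg = self.config
        labels = np.asarray(labels, dtype=np.int64)
        sizes = np.bincount(labels, minlength=cfg.k)
        if sizes.min() < cfg.min_group_size:
            return cfg.penalty, None
        groups = self.groups_of(labels)
        scores = [self.group_score(g) for g in groups]
        vals = np.array([s.fitness for s in scores])
        total = float(vals.mean()) if cfg.aggregate == "mean" else float(vals.sum())
        pair, report = self.best_pair(labels)
        if cfg.weights.w_iso > 0:
            if report is None:
                total += cfg.penalty
            else:
                total += cfg.weights.w_iso * report.ratio
        return total, report

    def pair_bipartition_ari(self, labels: np.ndarray, truth_labels: Sequence) -> Optional[float]:
        """ARI of the best pair's induced bipartition against true labels,
        restricted to the datasets belonging to the two selected groups."""
        pair, _ = self.best_pair(labels)
        if pair is None:
            return None
        labels = np.asarray(labels)
        sel = (labels == pair[0]) | (labels == pair[1])
        if sel.sum() < 2:
            return None
        pred = labels[sel]
        truth = np.asarray(truth_labels)[sel]
        return adjusted_rand_index(truth, pred)


def partition_fitness(labels, pool: ObservationTable, config: GAConfig) -> float:
    """Convenience wrapper; builds a fresh evaluator per call.

    Accepts 0-based labels, or 1-based vectors whose values span {1..k}.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) and labels.min() >= 1 and labels.max() == config.k:
        labels = labels - 1
    ev = PartitionEvaluator(pool, config)
    return ev.partition_fitness(labels)


def _tournament(rng, fits, size):
    idx = rng.integers(0, len(fits), size=size)
    return idx[np.argmax(fits[idx])]


def _hill_climb(labels: np.ndarray, ev: PartitionEvaluator, max_passes: int = 10):
    """Deterministic steepest single-dataset reassignment until a local optimum.

    Cheap thanks to the evaluator's group cache; used as a final polish of the
    GA's best partition so the returned partition is locally optimal under
    single-dataset moves.
    """
    labels = labels.copy()
    best = ev.partition_fitness(labels)
    k = ev.config.k
    for _ in range(max_passes):
        improved = False
        for i in range(len(labels)):
            current = labels[i]
            best_g, best_f = current, best
            for g in range(k):
                if g == current:
                    continue
                labels[i] = g
                f = ev.partition_fitness(labels)
                if f > best_f + 1e-12:
                    best_g, best_f = g, f
            labels[i] = best_g
            if best_g != current:
                best = best_f
                improved = True
        if not improved:
            break
    return labels, best


def evolve(
    pool: ObservationTable,
    config: GAConfig,
    truth_labels: Sequence = None,
    evaluator: PartitionEvaluator = None,
) -> tuple[Partition, list[TrajectoryRecord]]:
    """Run the GA; returns the best partition ever seen and the trajectory.

    The pool must already be on a common scale (see
    :func:`ssir.merging.scale_to_reference`); :class:`GroupingModel` wires the
    scaling in.  Fixed seed => bit-identical trajectory.
    """
    cfg = config
    n = pool.n_datasets
    if n < cfg.k * cfg.min_group_size:
        raise ValueError(
            f"pool has {n} datasets; need at least k*min_group_size = "
            f"{cfg.k * cfg.min_group_size}"
        )
    ev = evaluator or PartitionEvaluator(pool, cfg)
    ss = np.random.SeedSequence(cfg.seed)
    ss_ga, _ = ss.spawn(2)
    rng = np.random.default_rng(ss_ga)
    pm = cfg.mutation_prob if cfg.mutation_prob is not None else 1.0 / n

    pop = rng.integers(0, cfg.k, size=(cfg.population_size, n), dtype=np.int64)
    fits = np.array([ev.partition_fitness(ind) for ind in pop])

    best_idx = int(np.argmax(fits))
    best_labels = pop[best_idx].copy()
    best_fit = float(fits[best_idx])

    trajectory: list[TrajectoryRecord] = []

    def record(gen):
        _, rep = ev.partition_details(best_labels)
        ari = (ev.pair_bipartition_ari(best_labels, truth_labels)
               if truth_labels is not None else None)
        trajectory.append(
            TrajectoryRecord(
                generation=gen,
                best_fitness=best_fit,
                mean_fitness=float(fits.mean()),
                best_labels=[int(x) for x in best_labels],
                iso=rep.to_dict() if rep is not None else None,
                truth_ari=ari,
            )
        )

    record(0)
    for gen in range(1, cfg.generations + 1):
        order = np.argsort(-fits, kind="stable")
        new = [pop[i].copy() for i in order[: cfg.elitism_count]]
        while len(new) < cfg.population_size:
            a = pop[_tournament(rng, fits, cfg.tournament_size)].copy()
            b = pop[_tournament(rng, fits, cfg.tournament_size)].copy()
            if rng.random() < cfg.crossover_prob:
                mask = rng.random(n) < 0.5
                a[mask], b[mask] = b[mask], a[mask].copy()
            for child in (a, b):
                mut = rng.random(n) < pm
                if mut.any():
                    child[mut] = (child[mut] + rng.integers(1, cfg.k, size=int(mut.sum()))) % cfg.k
                if len(new) < cfg.population_size:
                    new.append(child)
        pop = np.stack(new)
        fits = np.array([ev.partition_fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if float(fits[gen_best]) > best_fit:
            best_fit = float(fits[gen_best])
            best_labels = pop[gen_best].copy()
        record(gen)

    if cfg.polish:
        polished, polished_fit = _hill_climb(best_labels, ev)
        if polished_fit > best_fit:
            best_labels, best_fit = polished, polished_fit
            record(cfg.generations + 1)

    return Partition(best_labels, ev.dataset_ids, cfg.k), trajectory


def select_best_pair(partition: Partition, pool: ObservationTable, config: GAConfig,
                     evaluator: PartitionEvaluator = None):
    """Maximal-ISO-ratio unordered group pair of a partition, plus manifest.

    Returns ((gA, gB), IsoReport, manifest) where the manifest lists both
    native/derivative orderings: with isomorphous differences alone there is
    no way to tell a priori which group is which.
    """
    ev = evaluator or PartitionEvaluator(pool, config)
    pair, report = ev.best_pair(partition.labels)
    if pair is None:
        raise ValueError(
            "no group pair with a defined ISO ratio; consider a smaller "
            "iso_min_common or a different number of groups"
        )
    manifest = {
        "pair": list(pair),
        "orderings": [
            {"native": pair[0], "derivative": pair[1]},
            {"native": pair[1], "derivative": pair[0]},
        ],
        "iso": report.to_dict(),
    }
    return pair, report, manifest


# ---------------------------------------------------------------------------
# model / results surface


class GroupingModel:
    """Grouping of a pool of partial serial-crystallography datasets.

    Wraps reference selection, common scaling and the GA into a fit()
    interface::

        model = GroupingModel(pool, GAConfig(k=4, seed=1))
        res = model.fit()
        print(res.summary())
    """

    def __init__(self, pool: ObservationTable, config: GAConfig = None,
                 truth=None, prescaled: bool = False):
        self.config = config or GAConfig()
        self.raw_pool = pool
        self.truth = truth
        if prescaled:
            self.pool = pool
            self.reference = None
            self.scales = {d: 1.0 for d in pool.dataset_ids}
        else:
            self.reference = merging.choose_reference(pool)
            self.scales = merging.scale_to_reference(pool, self.reference)
            self.pool = merging.apply_scales(pool, self.scales)
        self.evaluator = PartitionEvaluator(self.pool, self.config)

    @classmethod
    def from_directory(cls, directory, config: GAConfig = None, truth=None) -> "GroupingModel":
        from .io import read_pool

        return cls(read_pool(directory), config=config, truth=truth)

    def fit(self) -> "GroupingResults":
        truth_labels = (self.truth.labels_for(self.pool.dataset_ids)
                        if self.truth is not None else None)
        partition, trajectory = evolve(self.pool, self.config,
                                       truth_labels=truth_labels,
                                       evaluator=self.evaluator)
        return GroupingResults(self, partition, trajectory)


class GroupingResults:
    """Best partition found by the GA, with diagnostics and exports."""

    def __init__(self, model: GroupingModel, partition: Partition,
                 trajectory: list[TrajectoryRecord]):
        self.model = model
        self.partition = partition
        self.trajectory = trajectory
        self.best_fitness = trajectory[-1].best_fitness if trajectory else None
        self._pair = None

    @property
    def config(self) -> GAConfig:
        return self.model.config

    def best_pair(self):
        if self._pair is None:
            self._pair = select_best_pair(self.partition, self.model.pool,
                                          self.config, evaluator=self.model.evaluator)
        return self._pair

    def merged_groups(self) -> dict[int, MergedGroup]:
        out = {}
        for g in range(self.config.k):
            members = self.partition.members(g)
            if members:
                out[g] = merging.merge(self.model.pool, members)
        return out

    def group_stats(self) -> dict[int, merging.MergeStats]:
        shells = self.model.evaluator.shells
        return {
            g: compute_stats(grp, self.model.pool, shells=shells,
                             cc_seed=self.config.seed)
            for g, grp in self.merged_groups().items()
        }

    def truth_ari(self) -> Optional[float]:
        if self.model.truth is None:
            return None
        truth_labels = self.model.truth.labels_for(self.model.pool.dataset_ids)
        return self.model.evaluator.pair_bipartition_ari(self.partition.labels, truth_labels)

    def summary(self) -> str:
        lines = []
        pair, report, _ = self.best_pair()
        lines.append("Serial SIR grouping results")
        lines.append("===========================")
        lines.append(f"datasets: {self.model.pool.n_datasets}   groups: {self.config.k}   "
                     f"seed: {self.config.seed}")
        lines.append(f"best fitness: {self.best_fitness:.3f}   "
                     f"generations: {len(self.trajectory) - 1}")
        sizes = self.partition.group_sizes()
        lines.append("group sizes: " + ", ".join(
            f"g{g + 1}={int(s)}" for g, s in enumerate(sizes)))
        fmt = lambda v, spec: ("n/a" if v is None else format(v, spec))
        lines.append(
            f"best pair: g{pair[0] + 1}/g{pair[1] + 1}   "
            f"R_inter={fmt(report.r_inter, '.4f')}   "
            f"R_intra_avg={fmt(report.r_intra_avg, '.4f')}   "
            f"ratio={fmt(report.ratio, '.3f')}{' (capped)' if report.capped else ''}"
        )
        ari = self.truth_ari()
        if ari is not None:
            lines.append(f"truth ARI (best pair): {ari:.3f}")
        lines.append("")
        lines.append(f"{'group':>5} {'n_ds':>5} {'uniq':>7} {'compl':>7} {'mult':>7} "
                     f"{'R_meas':>8} {'CC1/2':>7} {'<I/sig>':>8}")
        for g, st in sorted(self.group_stats().items()):
            lines.append(
                f"{g + 1:>5} {len(self.partition.members(g)):>5} {st.n_unique:>7} "
                f"{100 * st.completeness:>6.1f}% {st.multiplicity:>7.2f} "
                f"{st.r_meas if st.r_meas is not None else float('nan'):>8.4f} "
                f"{st.cc_half if st.cc_half is not None else float('nan'):>7.4f} "
                f"{st.i_over_sig:>8.2f}"
            )
        return "\n".join(lines)

    def plot_trajectory(self, path=None):
        """Best/mean fitness per generation; returns the matplotlib figure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        gens = [t.generation for t in self.trajectory]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(gens, [t.best_fitness for t in self.trajectory], label="best")
        ax.plot(gens, [t.mean_fitness for t in self.trajectory], label="population mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("fitness")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
        return fig

    def save(self, directory) -> dict:
        """Write partition CSV, trajectory JSONL, pairing manifest, per-group
        stats CSV and SHELX HKLF-4 exports; returns the path map."""
        from pathlib import Path

        import pandas as pd

        from .io import write_shelx_hkl

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}

        part = pd.DataFrame({
            "dataset_id": self.partition.dataset_ids,
            "group": self.partition.one_based,
        })
        paths["partition"] = directory / "partition.csv"
        part.to_csv(paths["partition"], index=False)

        paths["trajectory"] = directory / "trajectory.jsonl"
        with open(paths["trajectory"], "w") as fh:
            for rec in self.trajectory:
                fh.write(rec.to_json() + "\n")

        pair, report, manifest = self.best_pair()
        paths["manifest"] = directory / "pairing_manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))

        rows = []
        for g, st in sorted(self.group_stats().items()):
            row = {"group": g + 1, **st.to_row()}
            rows.append(row)
        paths["stats"] = directory / "group_stats.csv"
        pd.DataFrame(rows).to_csv(paths["stats"], index=False)

        for g, grp in self.merged_groups().items():
            p = directory / f"group_{g + 1}.hkl"
            write_shelx_hkl(grp, p)
            paths[f"shelx_group_{g + 1}"] = p
        return paths
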