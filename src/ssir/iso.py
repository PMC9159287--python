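"""The isomorphism (ISO) fitness term.

A classical SIR sanity check compares the R value *between* candidate native
and derivative datasets against the internal (noise-level) R of each dataset:
a real isomorphous signal gives an inter-group R well above the intra-group
noise, while the absolute inter-group R must not be excessively high (gross
non-isomorphism).  The ISO term encodes this as

    ISO = w_iso * min(R_inter / R_intra_avg, ratio_cap)

with R_inter the between-group R on intensities after least-squares scaling,
and R_intra_avg the mean of the two groups' inner-shell R_meas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .merging import MergedGroup

__all__ = ["IsoReport", "r_inter", "iso_ratio", "iso_term", "ISO_MIN_COMMON", "RATIO_CAP"]

ISO_MIN_COMMON = 50   # minimum shared unique reflections for a defined ISO
RATIO_CAP = 10.0      # "not excessively high" guard on the inter:intra ratio


@dataclass
class IsoReport:
    """Ingredients and value of the ISO ratio for one group pair."""

    r_inter: Optional[float]
    r_intra_avg: Optional[float]
    ratio: Optional[float]
    n_common: int
    capped: bool = False
    pair: tuple = None

    @property
    def defined(self) -> bool:
        return self.ratio is not None

    def to_dict(self) -> dict:
        return {
            "r_inter": self.r_inter,
            "r_intra_avg": self.r_intra_avg,
            "ratio": self.ratio,
            "n_common": self.n_common,
            "capped": self.capped,
            "pair": list(self.pair) if self.pair is not None else None,
        }


def _common_intensities(a: MergedGroup, b: MergedGroup):
    """Intensities of reflections present in both groups (matched order)."""
    key = lambda hkl: (hkl[:, 0].astype(np.int64) * (1 << 21) + hkl[:, 1]) * (1 << 21) + hkl[:, 2]
    ka, kb = key(a.hkl), key(b.hkl)
    common, ia, ib = np.intersect1d(ka, kb, return_indices=True)
    return a.intensity[ia], b.intensity[ib]


def _r_between(i_a: np.ndarray, i_b: np.ndarray, symmetric: bool = False) -> Optional[float]:
    """R between two intensity vectors after least-squares scaling of B onto A:
    sum|I_A - k I_B| / sum((I_A + k I_B)/2).  ``symmetric`` averages both
    scaling directions."""
    denom_b = float(np.sum(i_b * i_b))
    if denom_b <= 0:
        return None
    k = float(np.sum(i_a * i_b) / denom_b)
    num = np.abs(i_a - k * i_b).sum()
    den = ((i_a + k * i_b) / 2.0).sum()
    if den <= 0:
        return None
    r = float(num / den)
    if symmetric:
        r_swap = _r_between(i_b, i_a, symmetric=False)
        if r_swap is None:
            return None
        r = 0.5 * (r + r_swap)
    return r


def r_inter(
    group_a: MergedGroup,
    group_b: MergedGroup,
    min_common: int = ISO_MIN_COMMON,
    symmetric: bool = False,
) -> tuple[Optional[float], int]:
    """Between-group R on common reflections; (None, n_common) when undefined."""
    i_a, i_b = _common_intensities(group_a, group_b)
    n_common = len(i_a)
    if n_common < min_common:
        return None, n_common
    return _r_between(i_a, i_b, symmetric=symmetric), n_common


def iso_ratio(
    r_inter_value: Optional[float],
    r_intra_avg: Optional[float],
    ratio_cap: float = RATIO_CAP,
) -> tuple[Optional[float], bool]:
    """Inter:intra ratio with the cap; handles the degenerate noise-free limits."""
    if r_inter_value is None or r_intra_avg is None:
        return None, False
    if r_inter_value <= 0:
        return 0.0, False
    if r_intra_avg <= 0:
        return ratio_cap, True
    ratio = r_inter_value / r_intra_avg
    if ratio > ratio_cap:
        return ratio_cap, True
    return ratio, False


def iso_term(
    group_a: MergedGroup,
    group_b: MergedGroup,
    inner_rmeas_a: Optional[float],
    inner_rmeas_b: Optional[float],
    w_iso: float,
    min_common: int = ISO_MIN_COMMON,
    ratio_cap: float = RATIO_CAP,
    symmetric: bool = False,
) -> tuple[Optional[float], IsoReport]:
    """ISO = w_iso * min(R_inter / R_intra_avg, cap); (None, report) if undefined."""
    r_int, n_common = r_inter(group_a, group_b, min_common=min_common, symmetric=symmetric)
    if inner_rmeas_a is None or inner_rmeas_b is None:
        r_intra = None
    else:
        r_intra = 0.5 * (inner_rmeas_a + inner_rmeas_b)
    ratio, capped = iso_ratio(r_int, r_intra, ratio_cap)
    report = IsoReport(r_int, r_intra, ratio, n_common, capped)
    if w_iso == 0:
        return 0.0, report
    if ratio is None:
        return None, report
    return w_iso * ratio, report
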