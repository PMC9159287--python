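"""Space-group operators, reflection symmetry and unique-reflection sets.

Support is a built-in table of general-position operators for the handful of
space groups this tool needs (P1, P212121, P43212, I213, P6122) rather than a
general symbol parser.  Point-group action on reflection indices is derived
from the rotation parts: a rotation R acting on fractional coordinates sends
h (row vector) to h.R, i.e. column vectors transform by R^T.  Friedel mates
are always merged (no anomalous signal is used anywhere in this package).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cells import UnitCell, resolution

__all__ = [
    "SymmetrySetting",
    "get_symmetry",
    "space_group_number",
    "map_to_asu",
    "enumerate_unique",
    "SPACE_GROUPS",
]


def _op(rot, trans=(0, 0, 0)):
    return np.array(rot, dtype=int), np.array(trans, dtype=float)


# General-position operators (rotation matrix acting on fractional xyz,
# translation in fractions).  Sources: standard ITA settings.
_I = ((1, 0, 0), (0, 1, 0), (0, 0, 1))

_SG_OPS: dict[str, list] = {}

_SG_OPS["P1"] = [_op(_I)]

_SG_OPS["P212121"] = [  # No. 19
    _op(_I),
    _op(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0.5, 0, 0.5)),
    _op(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0, 0.5, 0.5)),
    _op(((1, 0, 0), (0, -1, 0), (0, 0, -1)), (0.5, 0.5, 0)),
]

_SG_OPS["P43212"] = [  # No. 96
    _op(_I),
    _op(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0, 0, 0.5)),
    _op(((0, -1, 0), (1, 0, 0), (0, 0, 1)), (0.5, 0.5, 0.75)),
    _op(((0, 1, 0), (-1, 0, 0), (0, 0, 1)), (0.5, 0.5, 0.25)),
    _op(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0.5, 0.5, 0.75)),
    _op(((1, 0, 0), (0, -1, 0), (0, 0, -1)), (0.5, 0.5, 0.25)),
    _op(((0, 1, 0), (1, 0, 0), (0, 0, -1)), (0, 0, 0)),
    _op(((0, -1, 0), (-1, 0, 0), (0, 0, -1)), (0, 0, 0.5)),
]

# No. 199 (I213): P213-style representatives plus body centering.
_P213_LIKE = [
    _op(_I),
    _op(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0.5, 0, 0.5)),
    _op(((-1, 0, 0), (0, 1, 0), (0, 0, -1)), (0, 0.5, 0.5)),
    _op(((1, 0, 0), (0, -1, 0), (0, 0, -1)), (0.5, 0.5, 0)),
    _op(((0, 0, 1), (1, 0, 0), (0, 1, 0))),
    _op(((0, 0, 1), (-1, 0, 0), (0, -1, 0)), (0.5, 0.5, 0)),
    _op(((0, 0, -1), (-1, 0, 0), (0, 1, 0)), (0.5, 0, 0.5)),
    _op(((0, 0, -1), (1, 0, 0), (0, -1, 0)), (0, 0.5, 0.5)),
    _op(((0, 1, 0), (0, 0, 1), (1, 0, 0))),
    _op(((0, -1, 0), (0, 0, 1), (-1, 0, 0)), (0, 0.5, 0.5)),
    _op(((0, 1, 0), (0, 0, -1), (-1, 0, 0)), (0.5, 0.5, 0)),
    _op(((0, -1, 0), (0, 0, -1), (1, 0, 0)), (0.5, 0, 0.5)),
]
_SG_OPS["I213"] = _P213_LIKE + [
    _op(rot, (tr + np.array([0.5, 0.5, 0.5])) % 1.0) for rot, tr in _P213_LIKE
]

_SG_OPS["P6122"] = [  # No. 178 (hexagonal axes)
    _op(_I),
    _op(((0, -1, 0), (1, -1, 0), (0, 0, 1)), (0, 0, 1 / 3)),
    _op(((-1, 1, 0), (-1, 0, 0), (0, 0, 1)), (0, 0, 2 / 3)),
    _op(((-1, 0, 0), (0, -1, 0), (0, 0, 1)), (0, 0, 0.5)),
    _op(((0, 1, 0), (-1, 1, 0), (0, 0, 1)), (0, 0, 5 / 6)),
    _op(((1, -1, 0), (1, 0, 0), (0, 0, 1)), (0, 0, 1 / 6)),
    _op(((0, 1, 0), (1, 0, 0), (0, 0, -1)), (0, 0, 1 / 3)),
    _op(((1, -1, 0), (0, -1, 0), (0, 0, -1)), (0, 0, 0)),
    _op(((-1, 0, 0), (-1, 1, 0), (0, 0, -1)), (0, 0, 2 / 3)),
    _op(((0, -1, 0), (-1, 0, 0), (0, 0, -1)), (0, 0, 5 / 6)),
    _op(((-1, 1, 0), (0, 1, 0), (0, 0, -1)), (0, 0, 0.5)),
    _op(((1, 0, 0), (1, -1, 0), (0, 0, -1)), (0, 0, 1 / 6)),
]

_SG_NUMBERS = {"P1": 1, "P212121": 19, "P43212": 96, "P6122": 178, "I213": 199}
_SG_BY_NUMBER = {v: k for k, v in _SG_NUMBERS.items()}
_POINT_GROUP_NAME = {"P1": "1", "P212121": "222", "P43212": "422", "I213": "23", "P6122": "622"}

SPACE_GROUPS = tuple(_SG_OPS)


@dataclass(frozen=True)
class SymmetrySetting:
    """Point-group action on reflection indices for one space group.

    ``point_group_ops`` are integer 3x3 matrices acting on (h,k,l) column
    vectors; ``includes_friedel`` is always true here (isomorphous-only
    pipeline, no anomalous bookkeeping).
    """

    space_group_symbol: str
    point_group_ops: np.ndarray  # (M, 3, 3) int
    includes_friedel: bool = True
    _asu_ops: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def point_group_name(self) -> str:
        return _POINT_GROUP_NAME[self.space_group_symbol]

    @property
    def n_ops(self) -> int:
        return len(self.point_group_ops)

    def spacegroup_operators(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Full general-position (rotation, translation) list."""
        return [(r.copy(), t.copy()) for r, t in _SG_OPS[self.space_group_symbol]]

    def asu_ops(self) -> np.ndarray:
        """Point-group ops plus Friedel mates, stacked (2M,3,3)."""
        ops = self.point_group_ops
        return np.concatenate([ops, -ops], axis=0)


def _point_group_ops(symbol: str) -> np.ndarray:
    seen: dict[bytes, np.ndarray] = {}
    for rot, _ in _SG_OPS[symbol]:
        m = rot.T.copy()  # action on hkl columns
        seen.setdefault(m.tobytes(), m)
    ops = np.stack(list(seen.values()))
    return ops


def get_symmetry(symbol_or_number) -> SymmetrySetting:
    """Look up a SymmetrySetting by symbol ('P43212') or IT number (96)."""
    if isinstance(symbol_or_number, (int, np.integer)):
        if int(symbol_or_number) not in _SG_BY_NUMBER:
            raise KeyError(
                f"space-group number {symbol_or_number} not in built-in table "
                f"{sorted(_SG_BY_NUMBER)}"
            )
        symbol = _SG_BY_NUMBER[int(symbol_or_number)]
    else:
        symbol = str(symbol_or_number).replace(" ", "").replace("_", "")
        if symbol not in _SG_OPS:
            raise KeyError(f"space group '{symbol_or_number}' not in built-in table {SPACE_GROUPS}")
    return SymmetrySetting(symbol, _point_group_ops(symbol))


def space_group_number(symbol: str) -> int:
    return _SG_NUMBERS[str(symbol).replace(" ", "").replace("_", "")]


def _encode(hkl: np.ndarray) -> np.ndarray:
    """Monotone int64 key for lexicographic comparison of hkl triples."""
    h = hkl.astype(np.int64)
    base = np.int64(1 << 21)
    off = base // 2
    return ((h[..., 0] + off) * base + (h[..., 1] + off)) * base + (h[..., 2] + off)


def map_to_asu(h, k=None, l=None, sym: SymmetrySetting = None):
    """Map reflections to the lexicographically greatest symmetry equivalent.

    Friedel mates are always included.  Accepts either scalars
    ``map_to_asu(h, k, l, sym)`` or an (N,3) array ``map_to_asu(hkl, sym=sym)``.
    Idempotent and constant on every symmetry orbit.
    """
    if k is None and l is None:
        hkl = np.asarray(h, dtype=np.int64)
    elif isinstance(k, SymmetrySetting) and sym is None:
        sym, hkl = k, np.asarray(h, dtype=np.int64)
    else:
        hkl = np.array([h, k, l], dtype=np.int64)
    if sym is None:
        raise TypeError("a SymmetrySetting is required")
    single = hkl.ndim == 1
    hkl = np.atleast_2d(hkl)
    ops = sym.asu_ops()  # (M,3,3)
    cand = np.einsum("mij,nj->mni", ops, hkl)  # (M,N,3)
    keys = _encode(cand)  # (M,N)
    best = np.argmax(keys, axis=0)
    out = cand[best, np.arange(hkl.shape[0])]
    if single:
        return tuple(int(x) for x in out[0])
    return out


def enumerate_unique(cell: UnitCell, sym: SymmetrySetting, d_min: float, d_max: float = np.inf) -> np.ndarray:
    """All unique (ASU) reflections with d_min <= d <= d_max, as an (N,3) array.

    The index bound along axis i is a_i/d_min, which is exact for any cell
    (max |h_i| subject to |s| <= 1/d equals sqrt(G_ii)/d).
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    if d_min >= d_max:
        return np.empty((0, 3), dtype=np.int64)
    nmax = np.floor(cell.lengths / d_min).astype(int) + 1
    ax = [np.arange(-n, n + 1) for n in nmax]
    hh, kk, ll = np.meshgrid(*ax, indexing="ij")
    hkl = np.column_stack([hh.ravel(), kk.ravel(), ll.ravel()]).astype(np.int64)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = resolution(hkl, cell)
    keep = (d >= d_min - 1e-9) & (d <= d_max + 1e-9)
    hkl = hkl[keep]
    asu = map_to_asu(hkl, sym=sym)
    uniq = np.unique(_encode(asu))
    base = np.int64(1 << 21)
    off = base // 2
    out = np.empty((uniq.size, 3), dtype=np.int64)
    out[:, 2] = uniq % base - off
    rest = uniq // base
    out[:, 1] = rest % base - off
    out[:, 0] = rest // base - off
    return out
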