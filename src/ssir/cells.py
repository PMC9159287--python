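"""Unit-cell geometry: metric tensors and d-spacings.

All lengths are in Angstrom, all angles in degrees. The reciprocal metric
tensor is obtained by inverting the direct metric tensor, so the same code
serves every crystal system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UnitCell", "resolution"]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: edge lengths a, b, c (A) and angles (deg)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        # positive-definiteness of the metric is checked lazily via Cholesky
        g = self.metric_tensor()
        try:
            np.linalg.cholesky(g)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - exotic cells
            raise ValueError("unit-cell metric tensor is not positive definite") from exc

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma], dtype=float)

    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, A^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = np.cos(np.radians(self.angles))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal-space metric tensor G* = G^-1 (A^-2)."""
        return np.linalg.inv(self.metric_tensor())

    def volume(self) -> float:
        return float(np.sqrt(np.linalg.det(self.metric_tensor())))

    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with Cartesian coordinates = M @ fractional (standard PDB
        convention: a along x, b in the xy plane)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = np.cos(np.radians(self.angles))
        sg = np.sin(np.radians(self.gamma))
        v = self.volume()
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, v / (a * b * sg)],
            ]
        )

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """d-spacing (A) for one or many (h,k,l) triples."""
        return resolution(hkl, self)

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


def resolution(hkl, cell: UnitCell):
    """d-spacing d = 1/|s| with s from the reciprocal metric tensor.

    Accepts a single (h,k,l) triple or an (N,3) array; (0,0,0) raises for a
    single triple, and yields inf entries for array input.
    """
    h = np.asarray(hkl, dtype=float)
    single = h.ndim == 1
    h = np.atleast_2d(h)
    gstar = cell.reciprocal_metric_tensor()
    s2 = np.einsum("ni,ij,nj->n", h, gstar, h)
    if single:
        if s2[0] <= 0:
            raise ValueError("resolution undefined for (0,0,0)")
        return float(1.0 / np.sqrt(s2[0]))
    with np.errstate(divide="ignore"):
        return np.where(s2 > 0, 1.0 / np.sqrt(np.maximum(s2, 1e-300)), np.inf)
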