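"""Unit cells and d-spacings.

A :class:`UnitCell` holds the six lattice parameters and provides the
reciprocal metric tensor, from which the resolution (d-spacing in Å) of any
Miller index follows as ``d = 1/|s|`` with ``|s|^2 = h^T G* h``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["UnitCell", "resolution_of"]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError(f"cell lengths must be positive, got {self}")
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValueError(f"cell angle {name}={v} outside (0, 180)")
        # positive-definite metric <=> positive cell volume
        if self._volume_factor() <= 0:
            raise ValueError(f"degenerate cell (non positive-definite metric): {self}")

    def _volume_factor(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return self.a * self.b * self.c * math.sqrt(self._volume_factor())

    @property
    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (3×3, Å²)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        a, b, c = self.a, self.b, self.c
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G⁻¹ (Å⁻²)."""
        return np.linalg.inv(self.metric_tensor)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """d-spacings (Å) for an (n, 3) or (3,) integer index array."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        s2 = np.einsum("ni,ij,nj->n", h, self.reciprocal_metric_tensor, h)
        if np.any(s2 <= 0):
            raise ValueError("d-spacing undefined for the (0,0,0) index")
        d = 1.0 / np.sqrt(s2)
        return d if np.asarray(hkl).ndim == 2 else float(d[0])

    def close_to(self, other: "UnitCell", length_tol: float = 0.02, angle_tol: float = 2.0) -> bool:
        """True when each edge differs < `length_tol` (relative) and each angle < `angle_tol` degrees."""
        for x, y in ((self.a, other.a), (self.b, other.b), (self.c, other.c)):
            if abs(x - y) / y >= length_tol:
                return False
        for x, y in (
            (self.alpha, other.alpha),
            (self.beta, other.beta),
            (self.gamma, other.gamma),
        ):
            if abs(x - y) >= angle_tol:
                return False
        return True


def resolution_of(hkl, cell: UnitCell):
    """Resolution d = 1/|s| (Å) of a Miller index in a given cell.

    Accepts one index (3-tuple) or an (n, 3) array; (0,0,0) is rejected.
    """
    return cell.d_spacing(hkl)
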