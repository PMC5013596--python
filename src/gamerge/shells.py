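"""Resolution-shell schemes.

Statistics are reported per resolution shell.  The default scheme divides the
resolution range into ``n`` shells of equal reciprocal volume (equal spacing
in 1/d³), so each shell holds roughly the same number of unique reflections;
an explicit list of shell edges may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ShellScheme", "make_shells", "assign_shells"]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class ShellScheme:
    """Half-open resolution shells bounded by strictly decreasing d-edges (Å).

    Shell ``i`` covers d in (edges[i+1], edges[i]]; d-values beyond the
    low-resolution edge fall into the innermost shell (shell 0), while
    d-values finer than the last edge are excluded.
    """

    edges: tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 4:
            raise ValueError("need at least 3 shells (4 edges): inner and outer must differ")
        if any(e <= 0 for e in edges):
            raise ValueError("shell edges must be positive d-spacings")
        if any(a <= b for a, b in zip(edges, edges[1:])):
            raise ValueError(f"shell edges must be strictly decreasing, got {edges}")

    @property
    def n_shells(self) -> int:
        return len(self.edges) - 1

    @property
    def d_max(self) -> float:
        return self.edges[0]

    @property
    def d_min(self) -> float:
        return self.edges[-1]


def make_shells(d_max: float, d_min: float, n: int = 10) -> ShellScheme:
    """Equal reciprocal-volume shells: edges equally spaced in 1/d³."""
    if not d_max > d_min > 0:
        raise ValueError(f"need d_max > d_min > 0, got {d_max}, {d_min}")
    if n < 3:
        raise ValueError("at least 3 shells required (inner and outer shells must differ)")
    s3 = np.linspace(d_max**-3, d_min**-3, n + 1)
    return ShellScheme(edges=tuple(s3 ** (-1.0 / 3.0)))


def assign_shells(d: np.ndarray, scheme: ShellScheme) -> np.ndarray:
    """Shell index for each d-spacing; -1 for d beyond the resolution limit."""
    d = np.asarray(d, dtype=float)
    inner_bounds = 1.0 / np.array(scheme.edges[1:-1])  # ascending in 1/d
    x = 1.0 / d
    shell = np.searchsorted(inner_bounds, x, side="left")
    shell[x > (1.0 / scheme.d_min) * (1.0 + _REL_TOL)] = -1
    return shell
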