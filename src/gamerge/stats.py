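"""Per-shell and aggregate merging statistics.

Implements the standard crystallographic data-quality metrics for a merged
group of sub-data sets:

* R_merge = sum_h sum_i |I_hi - <I_h>| / sum_h sum_i I_hi, over reflections
  measured at least twice, with the plain (unweighted) mean in the numerator;
* R_meas, the multiplicity-independent variant with the per-reflection
  factor sqrt(n_h / (n_h - 1)) (Diederichs & Karplus);
* <I/sigma(I)> in two variants: the merged-reflection ratio
  mean_I / sigma_mean (error propagation makes this grow with multiplicity)
  and the plain per-observation mean of I/sigma, which is essentially
  independent of multiplicity — the behaviour processed experimental tables
  show;
* multiplicity, completeness against the theoretical unique count;
* CC1/2, the Pearson correlation between random half-set means;
* SigAno, the mean anomalous difference between Friedel mates in units of
  its estimated standard deviation, and CC_anom, the correlation of
  half-set anomalous differences.

Statistics that need a correlation are marked undefined (None) in shells
with fewer than three eligible reflections, never reported as zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .cell import UnitCell
from .merge import MergedGroup
from .shells import ShellScheme, assign_shells
from .symmetry import reduce_indices

__all__ = ["MergingStats", "ShellStats", "compute_stats", "theoretical_count"]

MIN_CORR_REFLECTIONS = 3
ENUMERATION_LIMIT = 10**8


@dataclass
class ShellStats:
    """Statistics of one resolution shell (or of all data pooled)."""

    d_max: float
    d_min: float
    n_unique: int = 0
    n_obs: int = 0
    completeness: float | None = None  # %
    multiplicity: float | None = None
    r_merge: float | None = None  # %
    r_meas: float | None = None  # %
    mean_i_over_sigma: float | None = None  # merged: mean of mean_I / sigma_mean
    mean_i_over_sigma_obs: float | None = None  # per-observation mean of I/sigma
    cc_half: float | None = None  # %
    sig_ano: float | None = None
    cc_anom: float | None = None  # %

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class MergingStats:
    """Shell table plus overall row for one merged group."""

    shells: list[ShellStats]
    overall: ShellStats
    scheme: ShellScheme

    @property
    def inner(self) -> ShellStats:
        return self.shells[0]

    @property
    def outer(self) -> ShellStats:
        return self.shells[-1]

    def as_dict(self) -> dict:
        return {
            "edges": list(self.scheme.edges),
            "shells": [s.as_dict() for s in self.shells],
            "overall": self.overall.as_dict(),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.as_dict(), **kw)

    def table(self) -> str:
        """Plain-text per-shell table in the spirit of an XSCALE.LP summary."""
        cols = [
            ("RESOLUTION", lambda s: f"{s.d_max:7.2f} -{s.d_min:6.2f}"),
            ("NUNIQUE", lambda s: f"{s.n_unique:8d}"),
            ("NOBS", lambda s: f"{s.n_obs:9d}"),
            ("COMPLETE%", lambda s: _fmt(s.completeness)),
            ("MULT", lambda s: _fmt(s.multiplicity)),
            ("RMERGE%", lambda s: _fmt(s.r_merge)),
            ("RMEAS%", lambda s: _fmt(s.r_meas)),
            ("I/SIGMA", lambda s: _fmt(s.mean_i_over_sigma)),
            ("CC1/2%", lambda s: _fmt(s.cc_half)),
            ("SIGANO", lambda s: _fmt(s.sig_ano)),
            ("CCANOM%", lambda s: _fmt(s.cc_anom)),
        ]
        lines = ["  ".join(f"{name:>9s}" for name, _ in cols)]
        for s in self.shells + [self.overall]:
            lines.append("  ".join(f"{f(s):>9s}" for _, f in cols))
        lines[-1] += "   (overall)"
        return "\n".join(lines)


def _fmt(v) -> str:
    return "   --" if v is None else f"{v:9.2f}"


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < MIN_CORR_REFLECTIONS:
        return None
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        # no variance: perfectly correlated only if identical
        return 100.0 if np.allclose(x, y) else None
    return float(np.corrcoef(x, y)[0, 1] * 100.0)


@lru_cache(maxsize=32)
def _theoretical_count_cached(
    edges: tuple[float, ...], cell_key: tuple[float, ...], space_group_number: int
) -> tuple[int, ...]:
    cell = UnitCell(*cell_key)
    scheme = ShellScheme(edges)
    d_min = scheme.d_min
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    n_raw = (2 * hmax + 1) * (2 * kmax + 1) * (2 * lmax + 1)
    if n_raw > ENUMERATION_LIMIT:
        raise ResourceWarning(
            f"theoretical reflection enumeration of {n_raw} raw indices exceeds "
            f"{ENUMERATION_LIMIT}; use a coarser resolution limit"
        )
    h, k, l = np.mgrid[-hmax : hmax + 1, -kmax : kmax + 1, -lmax : lmax + 1]
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    inside = d >= d_min * (1.0 - 1e-9)
    hkl = hkl[inside]
    reduced, _ = reduce_indices(hkl, space_group_number, friedel_law=True)
    uniq = np.unique(reduced, axis=0)
    shell = assign_shells(cell.d_spacing(uniq), scheme)
    counts = np.bincount(shell[shell >= 0], minlength=scheme.n_shells)
    return tuple(int(c) for c in counts)


def theoretical_count(scheme: ShellScheme, cell: UnitCell, space_group_number: int) -> np.ndarray:
    """Number of theoretically observable unique reflections per shell.

    Brute-force enumeration of the reciprocal-lattice box out to the finest
    shell edge, reduced to asymmetric-unit representatives and counted per
    shell.  Systematic absences are not subtracted: the same denominator is
    applied to every merging group, so rankings are unaffected.  Results are
    cached per (shells, cell, space group).
    """
    cell_key = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    return np.array(_theoretical_count_cached(scheme.edges, cell_key, space_group_number))


def _shell_stats(
    mg: MergedGroup,
    sel_u: np.ndarray,
    sel_obs: np.ndarray,
    d_max: float,
    d_min: float,
    n_theoretical: int | None,
) -> ShellStats:
    st = ShellStats(d_max=d_max, d_min=d_min)
    n_unique = int(np.count_nonzero(sel_u))
    n_obs = int(np.sum(mg.n_obs[sel_u]))
    st.n_unique = n_unique
    st.n_obs = n_obs
    if n_unique == 0:
        return st
    if n_theoretical is not None and n_theoretical > 0:
        st.completeness = 100.0 * n_unique / n_theoretical
    st.multiplicity = n_obs / n_unique
    st.mean_i_over_sigma = float(np.mean(mg.mean_I[sel_u] / mg.sigma_mean[sel_u]))
    if np.any(sel_obs):
        st.mean_i_over_sigma_obs = float(np.mean(mg.obs_intensity[sel_obs] / mg.obs_sigma[sel_obs]))

    # R factors over multiply-measured reflections
    multi_u = sel_u & (mg.n_obs >= 2)
    obs_multi = sel_obs & multi_u[mg.obs_index]
    if np.any(obs_multi):
        dev = np.abs(mg.obs_intensity[obs_multi] - mg.mean_unweighted[mg.obs_index[obs_multi]])
        denom = float(np.sum(mg.obs_intensity[obs_multi]))
        if denom > 0:
            st.r_merge = 100.0 * float(np.sum(dev)) / denom
            n_h = mg.n_obs[mg.obs_index[obs_multi]].astype(float)
            st.r_meas = 100.0 * float(np.sum(np.sqrt(n_h / (n_h - 1.0)) * dev)) / denom

    # CC1/2 over reflections with both half means
    halves = multi_u & ~np.isnan(mg.half1_I) & ~np.isnan(mg.half2_I)
    st.cc_half = _pearson(mg.half1_I[halves], mg.half2_I[halves])

    if not mg.friedel_law:
        mates = sel_u & ~np.isnan(mg.mean_I_plus) & ~np.isnan(mg.mean_I_minus)
        if np.any(mates):
            dano = np.abs(mg.mean_I_plus[mates] - mg.mean_I_minus[mates])
            sd = np.sqrt(mg.sigma_plus[mates] ** 2 + mg.sigma_minus[mates] ** 2)
            st.sig_ano = float(np.mean(dano / sd))
        ano = sel_u & ~np.isnan(mg.ano_half1) & ~np.isnan(mg.ano_half2)
        st.cc_anom = _pearson(mg.ano_half1[ano], mg.ano_half2[ano])
    return st


def compute_stats(
    mg: MergedGroup,
    scheme: ShellScheme,
    space_group_number: int,
    with_completeness: bool = True,
) -> MergingStats:
    """Per-shell and overall merging statistics of a merged group.

    Reflections beyond the finest shell edge are excluded everywhere.
    ``with_completeness=False`` skips the theoretical enumeration (useful for
    toy data where the cell is not meaningful).
    """
    shell_u = assign_shells(mg.d, scheme)
    shell_obs = shell_u[mg.obs_index]
    theo = theoretical_count(scheme, mg.cell, space_group_number) if with_completeness else None

    shells = []
    for s in range(scheme.n_shells):
        shells.append(
            _shell_stats(
                mg,
                shell_u == s,
                shell_obs == s,
                scheme.edges[s],
                scheme.edges[s + 1],
                int(theo[s]) if theo is not None else None,
            )
        )
    overall = _shell_stats(
        mg,
        shell_u >= 0,
        shell_obs >= 0,
        scheme.d_max,
        scheme.d_min,
        int(np.sum(theo)) if theo is not None else None,
    )
    return MergingStats(shells=shells, overall=overall, scheme=scheme)
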