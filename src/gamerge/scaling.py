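"""Relative scaling of sub-data sets within one merging group.

Before merging, each sub-data set j is placed on a common scale through a
multiplicative factor k_j and, optionally, an isotropic B-factor:

    g_j(d) = k_j * exp(-2 * B_j * (1/(2d))^2) = k_j * exp(-B_j / (2 d^2))

The parameters minimise sum_h sum_j (I_hj / g_j(d) - <I_h>)^2 by alternating
least squares between the per-index reference means <I_h> and the per-subset
parameters; the first subset is anchored at k=1, B=0.  This deliberately
simple scaler (no error-model refitting, no outlier rejection) is sufficient
to rank merging groups, which is all the selection algorithm needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import SubDataset

logger = logging.getLogger(__name__)

__all__ = ["ScaleResult", "scale_group"]

MAX_ITER = 100
REL_TOL = 1e-10


@dataclass
class ScaleResult:
    """Per-subset scale parameters; ``usable[j]`` is False when subset j had
    no reflections in common with the rest of the group and must be excluded."""

    k: np.ndarray  # (n_subsets,)
    b: np.ndarray  # (n_subsets,) Å², zero when model="scale"
    usable: np.ndarray  # (n_subsets,) bool
    n_iter: int = 0
    converged: bool = True

    def scale_factors(self, subset_index: np.ndarray, d: np.ndarray) -> np.ndarray:
        """g_j(d) evaluated per observation."""
        k = self.k[subset_index]
        b = self.b[subset_index]
        return k * np.exp(-b / (2.0 * d * d))


def _encode(hkl: np.ndarray) -> np.ndarray:
    h = hkl.astype(np.int64)
    m = int(np.abs(h).max(initial=0)) + 1
    base = 2 * m + 1
    return (h[:, 0] * base + h[:, 1]) * base + h[:, 2]


def scale_group(group: Sequence[SubDataset], model: str = "scale", rel_tol: float = REL_TOL) -> ScaleResult:
    """Fit relative scales for the sub-data sets of one merging group.

    Parameters
    ----------
    group : reduced sub-data sets (``reduce_to_asu`` already applied).
    model : ``"scale"`` (k only, default) or ``"scale+B"``.

    A single-subset group returns the anchor values k=1, B=0.  Subsets that
    share no reduced index with the union of the others are flagged unusable.
    """
    if model not in ("scale", "scale+B"):
        raise ValueError(f"unknown scaling model {model!r}")
    if len(group) == 0:
        raise ValueError("empty group")
    for ds in group:
        if not ds.reduced:
            raise ValueError(f"subset {ds.id!r} not reduced to the asymmetric unit")
    n_sub = len(group)
    if n_sub == 1:
        return ScaleResult(k=np.ones(1), b=np.zeros(1), usable=np.ones(1, dtype=bool))

    keys = _encode(np.concatenate([ds.hkl_red for ds in group]))
    subset = np.concatenate([np.full(len(ds), j, dtype=np.int64) for j, ds in enumerate(group)])
    intensity = np.concatenate([ds.intensity for ds in group])
    inv_d2 = np.concatenate([1.0 / ds.d_spacings() ** 2 for ds in group])

    uniq, inv = np.unique(keys, return_inverse=True)
    n_uniq = len(uniq)

    # a subset is scalable iff it shares >= 1 unique index with another subset
    counts = np.bincount(inv, minlength=n_uniq)
    shared = counts[inv] >= 2
    # index shared by >=2 *observations* may still be within one subset; check subsets
    usable = np.zeros(n_sub, dtype=bool)
    order = np.lexsort((subset, inv))
    inv_s, sub_s = inv[order], subset[order]
    starts = np.flatnonzero(np.r_[True, inv_s[1:] != inv_s[:-1]])
    ends = np.r_[starts[1:], len(inv_s)]
    for s, e in zip(starts, ends):
        subs = np.unique(sub_s[s:e])
        if len(subs) >= 2:
            usable[subs] = True
    for j in np.flatnonzero(~usable):
        logger.warning("subset %r shares no reflections with the rest of the group; excluded", group[j].id)

    keep = usable[subset] & shared
    k = np.ones(n_sub)
    b = np.zeros(n_sub)
    if not np.any(keep):
        return ScaleResult(k=k, b=b, usable=usable, n_iter=0, converged=False)

    inv_k, sub_k = inv[keep], subset[keep]
    i_k, d2_k = intensity[keep], inv_d2[keep]
    n_iter = 0
    converged = False
    for n_iter in range(1, MAX_ITER + 1):
        g = k[sub_k] * np.exp(-b[sub_k] * d2_k / 2.0)
        corr = i_k / g
        mean = np.bincount(inv_k, weights=corr, minlength=n_uniq) / np.maximum(
            np.bincount(inv_k, minlength=n_uniq), 1
        )
        m = mean[inv_k]
        k_new, b_new = k.copy(), b.copy()
        if model == "scale":
            for j in np.flatnonzero(usable):
                sel = sub_k == j
                num = np.dot(i_k[sel], i_k[sel])
                den = np.dot(i_k[sel], m[sel])
                if den > 0:
                    k_new[j] = num / den
                else:  # singular/negative system: median-ratio fallback
                    pos = sel & (m > 0) & (i_k > 0)
                    k_new[j] = np.median(i_k[pos] / m[pos]) if np.any(pos) else 1.0
        else:
            # log-linear fit log(I/m) = log k - (B/2) * (1/d^2) on positive pairs
            for j in np.flatnonzero(usable):
                sel = sub_k == j
                pos = sel & (m > 0) & (i_k > 0)
                if np.count_nonzero(pos) < 2:
                    continue
                y = np.log(i_k[pos] / m[pos])
                x = d2_k[pos]
                A = np.column_stack([np.ones(len(x)), -x / 2.0])
                try:
                    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                except np.linalg.LinAlgError:
                    continue
                k_new[j] = np.exp(coef[0])
                b_new[j] = coef[1]
        # anchor the first usable subset at k=1, B=0
        anchor = int(np.flatnonzero(usable)[0])
        b_new[usable] -= b_new[anchor]
        k_new[usable] /= k_new[anchor]
        delta = max(
            float(np.max(np.abs(k_new - k) / np.maximum(np.abs(k), 1e-12))),
            float(np.max(np.abs(b_new - b))) if model == "scale+B" else 0.0,
        )
        k, b = k_new, b_new
        if delta < rel_tol:
            converged = True
            break
    return ScaleResult(k=k, b=b, usable=usable, n_iter=n_iter, converged=converged)
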