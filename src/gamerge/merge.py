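"""Merging of scaled symmetry-equivalent observations.

After scaling, all observations of one merging group that share a reduced
Miller index are averaged with inverse-variance weights.  Alongside the
merged means, the merge keeps everything the statistics need:

* random half-set means per unique index (for CC1/2), from a seeded
  per-index random alternation of the observations;
* Friedel-separated means I+ / I- (for SigAno and CC_anom) when the data
  were integrated without assuming Friedel's law;
* the scaled raw observations and their index mapping (for R factors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .cell import UnitCell
from .datasets import SubDataset
from .scaling import ScaleResult

__all__ = ["MergedReflection", "MergedGroup", "merge_group"]


class MergedReflection(NamedTuple):
    """One unique reflection after merging (record view)."""

    hkl: tuple[int, int, int]
    mean_I: float
    sigma_mean: float
    n_obs: int
    half1_I: float | None
    half2_I: float | None
    mean_I_plus: float | None
    mean_I_minus: float | None
    d: float


@dataclass
class MergedGroup:
    """Column-wise merged reflections plus the scaled observations behind them."""

    cell: UnitCell
    friedel_law: bool
    # unique reflections
    hkl: np.ndarray  # (u, 3)
    mean_I: np.ndarray  # inverse-variance weighted
    sigma_mean: np.ndarray
    mean_unweighted: np.ndarray  # plain mean, used by the R-factor numerators
    n_obs: np.ndarray  # (u,)
    d: np.ndarray  # (u,)
    half1_I: np.ndarray  # NaN when n_obs < 2
    half2_I: np.ndarray
    # Friedel-separated (NaN-filled when friedel_law or a mate is missing)
    mean_I_plus: np.ndarray
    mean_I_minus: np.ndarray
    sigma_plus: np.ndarray
    sigma_minus: np.ndarray
    ano_half1: np.ndarray  # half-set anomalous differences, NaN when undefined
    ano_half2: np.ndarray
    # scaled raw observations
    obs_intensity: np.ndarray  # (N,)
    obs_sigma: np.ndarray
    obs_index: np.ndarray  # (N,) position into the unique arrays
    subset_ids: tuple[str, ...] = ()

    @property
    def n_unique(self) -> int:
        return len(self.mean_I)

    @property
    def n_observations(self) -> int:
        return len(self.obs_intensity)

    def __iter__(self) -> Iterator[MergedReflection]:
        for i in range(self.n_unique):
            yield MergedReflection(
                tuple(int(x) for x in self.hkl[i]),
                float(self.mean_I[i]),
                float(self.sigma_mean[i]),
                int(self.n_obs[i]),
                None if np.isnan(self.half1_I[i]) else float(self.half1_I[i]),
                None if np.isnan(self.half2_I[i]) else float(self.half2_I[i]),
                None if np.isnan(self.mean_I_plus[i]) else float(self.mean_I_plus[i]),
                None if np.isnan(self.mean_I_minus[i]) else float(self.mean_I_minus[i]),
                float(self.d[i]),
            )


def _encode(hkl: np.ndarray) -> np.ndarray:
    h = hkl.astype(np.int64)
    m = int(np.abs(h).max(initial=0)) + 1
    base = 2 * m + 1
    return (h[:, 0] * base + h[:, 1]) * base + h[:, 2]


def _group_means(inv: np.ndarray, values: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(inv, minlength=n).astype(float)
    sums = np.bincount(inv, weights=values, minlength=n)
    with np.errstate(invalid="ignore"):
        return sums / counts, counts


def _alternating_split(inv: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-group random alternation: 0/1 half label per observation.

    Observations of each group are put in random order and assigned halves
    alternately, so group sizes n split into ceil(n/2) / floor(n/2).
    """
    if len(inv) == 0:
        return np.empty(0, dtype=np.int64)
    noise = rng.random(len(inv))
    order = np.lexsort((noise, inv))
    inv_sorted = inv[order]
    starts = np.r_[True, inv_sorted[1:] != inv_sorted[:-1]]
    group_start = np.maximum.accumulate(np.where(starts, np.arange(len(inv)), 0))
    rank = np.arange(len(inv)) - group_start
    half = np.empty(len(inv), dtype=np.int64)
    half[order] = rank % 2
    return half


def merge_group(
    group: Sequence[SubDataset],
    scales: ScaleResult,
    rng_seed: int = 0,
) -> MergedGroup:
    """Scale and merge the observations of one merging group.

    ``rng_seed`` fixes the random half-set split so CC1/2 is reproducible.
    Subsets flagged unusable by the scaler are excluded.
    """
    if len(group) == 0:
        raise ValueError("empty group")
    cell = group[0].cell
    friedel_law = all(ds.friedel_law for ds in group)

    keep_sets = [ds for j, ds in enumerate(group) if scales.usable[j]]
    keep_j = np.flatnonzero(scales.usable)
    if not keep_sets:
        raise ValueError("no scalable subsets in group")
    hkl = np.concatenate([ds.hkl_red for ds in keep_sets])
    intensity = np.concatenate([ds.intensity for ds in keep_sets])
    sigma = np.concatenate([ds.sigma for ds in keep_sets])
    fsign = np.concatenate(
        [
            ds.friedel_sign
            if ds.friedel_sign is not None
            else np.zeros(len(ds), dtype=np.int64)
            for ds in keep_sets
        ]
    )
    subset = np.concatenate(
        [np.full(len(ds), j, dtype=np.int64) for j, ds in zip(keep_j, keep_sets)]
    )
    d_obs = np.concatenate([ds.d_spacings() for ds in keep_sets])

    g = scales.scale_factors(subset, d_obs)
    i_s = intensity / g
    sig_s = sigma / g

    keys = _encode(hkl)
    uniq_keys, first, inv = np.unique(keys, return_index=True, return_inverse=True)
    n_uniq = len(uniq_keys)
    uniq_hkl = hkl[first]
    d_uniq = cell.d_spacing(uniq_hkl)

    w = 1.0 / (sig_s * sig_s)
    wsum = np.bincount(inv, weights=w, minlength=n_uniq)
    mean_i = np.bincount(inv, weights=w * i_s, minlength=n_uniq) / wsum
    sigma_mean = 1.0 / np.sqrt(wsum)
    mean_unw, counts = _group_means(inv, i_s, n_uniq)
    n_obs = counts.astype(np.int64)

    rng = np.random.default_rng(rng_seed)
    half = _alternating_split(inv, rng)
    h_mean = np.full((2, n_uniq), np.nan)
    for hh in (0, 1):
        sel = half == hh
        mh, ch = _group_means(inv[sel], i_s[sel], n_uniq)
        h_mean[hh] = np.where(ch > 0, mh, np.nan)
    both = n_obs >= 2
    half1 = np.where(both, h_mean[0], np.nan)
    half2 = np.where(both, h_mean[1], np.nan)

    mean_plus = np.full(n_uniq, np.nan)
    mean_minus = np.full(n_uniq, np.nan)
    sig_plus = np.full(n_uniq, np.nan)
    sig_minus = np.full(n_uniq, np.nan)
    ano_half1 = np.full(n_uniq, np.nan)
    ano_half2 = np.full(n_uniq, np.nan)
    if not friedel_law:
        for sign, mean_arr, sig_arr in ((1, mean_plus, sig_plus), (-1, mean_minus, sig_minus)):
            sel = fsign == sign
            if not np.any(sel):
                continue
            ws = np.bincount(inv[sel], weights=w[sel], minlength=n_uniq)
            with np.errstate(invalid="ignore", divide="ignore"):
                m = np.bincount(inv[sel], weights=(w * i_s)[sel], minlength=n_uniq) / ws
                s = 1.0 / np.sqrt(ws)
            present = ws > 0
            mean_arr[present] = m[present]
            sig_arr[present] = s[present]
        # anomalous half differences: alternate split within each (index, sign)
        sub_key = inv * 2 + (fsign == 1)
        anom = fsign != 0
        half_a = np.zeros(len(inv), dtype=np.int64)
        if np.any(anom):
            half_a[anom] = _alternating_split(sub_key[anom], rng)
        cell_mean = np.full((2, 2, n_uniq), np.nan)  # [half, sign01, index]
        for hh in (0, 1):
            for s01, sign in ((0, -1), (1, 1)):
                sel = anom & (half_a == hh) & (fsign == sign)
                if not np.any(sel):
                    continue
                m, c = _group_means(inv[sel], i_s[sel], n_uniq)
                cell_mean[hh, s01] = np.where(c > 0, m, np.nan)
        ano_half1 = cell_mean[0, 1] - cell_mean[0, 0]
        ano_half2 = cell_mean[1, 1] - cell_mean[1, 0]

    return MergedGroup(
        cell=cell,
        friedel_law=friedel_law,
        hkl=uniq_hkl,
        mean_I=mean_i,
        sigma_mean=sigma_mean,
        mean_unweighted=mean_unw,
        n_obs=n_obs,
        d=np.atleast_1d(d_uniq),
        half1_I=half1,
        half2_I=half2,
        mean_I_plus=mean_plus,
        mean_I_minus=mean_minus,
        sigma_plus=sig_plus,
        sigma_minus=sig_minus,
        ano_half1=ano_half1,
        ano_half2=ano_half2,
        obs_intensity=i_s,
        obs_sigma=sig_s,
        obs_index=inv,
        subset_ids=tuple(ds.id for ds in keep_sets),
    )
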