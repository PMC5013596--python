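"""Synthetic sub-data-set pools with planted isomorphism structure.

The generator emulates the statistical shape of a serial-crystallography
pool without simulating diffraction physics:

* true intensities per unique reflection drawn from an acentric Wilson
  (exponential) distribution;
* groups of sub-data sets sharing a non-isomorphism perturbation — an
  index-wise log-normal multiplicative factor exp(delta * N(0,1)), fixed
  within the group, which lowers the between-group correlation and degrades
  mixed merges the way real non-isomorphism does;
* per-subset multiplicative scale k and isotropic B-factor;
* partial random coverage of the unique set (real pools range from a few
  percent to roughly half of the unique reflections per wedge);
* Gaussian measurement noise with sigma = sqrt(a*I + b) (Poisson-like with
  a floor), the reported sigma being the true noise width;
* optionally a planted anomalous signal splitting Friedel mates.

Ground truth (group labels, scales, true intensities) is recorded so tests
can check recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cell import UnitCell
from .datasets import SubDataset, reduce_to_asu, write_xds_ascii
from .shells import ShellScheme, make_shells
from .stats import theoretical_count
from .symmetry import reduce_indices

__all__ = ["SynthConfig", "GroundTruth", "generate_pool", "write_pool"]

MIN_EXPECTED_OBS = 10


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic pool.

    Defaults follow a desk-scale version of a serial experiment: a small
    orthorhombic cell, ~25% coverage per wedge (mid-range between sparse and
    half-complete pools), two observations per covered index, scales within
    a factor two, and Poisson-like noise around a mean intensity of 1000
    giving inner-shell signal-to-noise of a few tens.
    """

    n_subsets: int = 30
    cell: UnitCell = field(default_factory=lambda: UnitCell(30.0, 34.0, 36.0))
    space_group_number: int = 16  # P222 (Laue mmm)
    d_min: float = 2.0
    group_spec: tuple[tuple[int, float], ...] = ((20, 0.0), (10, 0.5))
    completeness_per_subset: float = 0.25
    scale_range: tuple[float, float] = (0.5, 2.0)
    b_range: tuple[float, float] = (0.0, 0.0)
    noise_a: float = 1.0
    noise_b: float = 1.0
    mean_intensity: float = 1000.0
    anomalous_frac: float = 0.0  # |F| perturbation: dI/I ~ 2*anomalous_frac
    anomalous_index_frac: float = 0.3
    track_friedel: bool = False  # Friedel bookkeeping even without a planted signal
    multiplicity_within_subset: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(size for size, _ in self.group_spec) != self.n_subsets:
            raise ValueError("group sizes must sum to n_subsets")
        if any(delta < 0 for _, delta in self.group_spec):
            raise ValueError("non-isomorphism level delta must be >= 0")
        if not 0.0 < self.completeness_per_subset <= 1.0:
            raise ValueError("completeness_per_subset must be in (0, 1]")
        if self.noise_a < 0 or self.noise_b < 0:
            raise ValueError("noise coefficients must be >= 0")
        if self.multiplicity_within_subset < 1:
            raise ValueError("multiplicity_within_subset must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    group_labels: list[int]  # per subset, 0-based group number
    k: list[float]
    b: list[float]
    hkl_unique: np.ndarray
    true_intensity: np.ndarray
    anomalous_indices: np.ndarray  # positions into hkl_unique
    config: SynthConfig

    @property
    def groups(self) -> list[list[int]]:
        out: dict[int, list[int]] = {}
        for i, g in enumerate(self.group_labels):
            out.setdefault(g, []).append(i)
        return [out[g] for g in sorted(out)]

    def as_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["cell"] = list(cfg["cell"].values())
        cfg["group_spec"] = [list(gs) for gs in self.config.group_spec]
        return {
            "config": cfg,
            "group_labels": self.group_labels,
            "k": self.k,
            "b": self.b,
            "hkl_unique": self.hkl_unique.tolist(),
            "true_intensity": self.true_intensity.tolist(),
            "anomalous_indices": self.anomalous_indices.tolist(),
        }


def _unique_asu_indices(cell: UnitCell, space_group_number: int, d_min: float) -> np.ndarray:
    """All unique asymmetric-unit indices with d >= d_min."""
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    h, k, l = np.mgrid[-hmax : hmax + 1, -kmax : kmax + 1, -lmax : lmax + 1]
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacing(hkl)
    hkl = hkl[d >= d_min * (1.0 - 1e-9)]
    reduced, _ = reduce_indices(hkl, space_group_number, friedel_law=True)
    return np.unique(reduced, axis=0)


def generate_pool(cfg: SynthConfig) -> tuple[list[SubDataset], GroundTruth]:
    """Generate a pool of sub-data sets; fully deterministic under cfg.seed.

    Returned subsets are already reduced to the asymmetric unit.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    uniq = _unique_asu_indices(cfg.cell, cfg.space_group_number, cfg.d_min)
    n_uniq = len(uniq)
    expected_obs = cfg.completeness_per_subset * n_uniq * cfg.multiplicity_within_subset
    if expected_obs < MIN_EXPECTED_OBS:
        raise ValueError(
            f"config yields ~{expected_obs:.1f} observations per subset (< {MIN_EXPECTED_OBS}); "
            "increase completeness, multiplicity or the resolution range"
        )
    i_true = rng.exponential(cfg.mean_intensity, size=n_uniq)

    anomalous = cfg.anomalous_frac > 0 or cfg.track_friedel
    if anomalous:
        # only acentric reflections carry an anomalous difference: centric
        # indices map to the same representative for both Friedel mates
        neg_signs = reduce_indices(-uniq, cfg.space_group_number, friedel_law=False)[1]
        acentric = np.flatnonzero(neg_signs == -1)
        if cfg.anomalous_frac > 0:
            n_ano = min(int(round(cfg.anomalous_index_frac * n_uniq)), len(acentric))
            ano_idx = rng.choice(acentric, size=n_ano, replace=False)
        else:
            ano_idx = np.empty(0, dtype=np.int64)
    else:
        ano_idx = np.empty(0, dtype=np.int64)
    # dI/I = 2 * dF/F for small anomalous perturbations of |F|
    dano = np.zeros(n_uniq)
    dano[ano_idx] = 2.0 * cfg.anomalous_frac * i_true[ano_idx]

    # per-group non-isomorphism perturbation, shared by all members of the group
    group_mult = []
    labels: list[int] = []
    for gidx, (size, delta) in enumerate(cfg.group_spec):
        mult = np.exp(delta * rng.standard_normal(n_uniq)) if delta > 0 else np.ones(n_uniq)
        group_mult.append(mult)
        labels.extend([gidx] * size)

    k_lo, k_hi = cfg.scale_range
    b_lo, b_hi = cfg.b_range
    k = rng.uniform(k_lo, k_hi, size=cfg.n_subsets)
    b = rng.uniform(b_lo, b_hi, size=cfg.n_subsets)
    k[0], b[0] = 1.0, 0.0  # match the scaler's anchor convention

    d_uniq = cfg.cell.d_spacing(uniq)
    pool: list[SubDataset] = []
    for j in range(cfg.n_subsets):
        n_cov = rng.binomial(n_uniq, cfg.completeness_per_subset)
        cov = rng.choice(n_uniq, size=max(n_cov, 1), replace=False)
        cov = np.repeat(cov, cfg.multiplicity_within_subset)
        base_i = i_true[cov] * group_mult[labels[j]][cov]
        if anomalous:
            sign = rng.choice(np.array([1, -1]), size=len(cov))
            base_i = base_i + sign * dano[cov] / 2.0
        else:
            sign = np.zeros(len(cov), dtype=np.int64)
        g = k[j] * np.exp(-b[j] / (2.0 * d_uniq[cov] ** 2))
        noiseless = base_i * g
        sigma = np.sqrt(cfg.noise_a * np.abs(noiseless) + cfg.noise_b)
        i_obs = noiseless + rng.standard_normal(len(cov)) * sigma
        # the format requires sigma > 0: noiseless configs report a tiny
        # nominal sigma while adding no noise at all
        sigma = np.maximum(sigma, 1e-6 * cfg.mean_intensity)
        hkl = uniq[cov]
        # emit the +h representative for sign +1 and the Friedel mate -h for
        # sign -1 so the files carry real anomalous bookkeeping
        if anomalous:
            hkl = hkl * np.where(sign[:, None] == -1, -1, 1)
        ds = SubDataset(
            id=f"subset_{j:03d}",
            cell=cfg.cell,
            space_group_number=cfg.space_group_number,
            friedel_law=not anomalous,
            hkl=hkl,
            intensity=i_obs,
            sigma=sigma,
        )
        reduce_to_asu(ds)
        pool.append(ds)
    truth = GroundTruth(
        group_labels=labels,
        k=[float(x) for x in k],
        b=[float(x) for x in b],
        hkl_unique=uniq,
        true_intensity=i_true,
        anomalous_indices=np.sort(ano_idx),
        config=cfg,
    )
    return pool, truth


def write_pool(pool: Sequence[SubDataset], truth: GroundTruth, out_dir: str | Path) -> list[Path]:
    """Write one XDS_ASCII-dialect file per subset plus ground_truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in pool:
        p = out_dir / f"{ds.id}.HKL"
        write_xds_ascii(ds, p)
        paths.append(p)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth.as_dict(), indent=1))
    return paths
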