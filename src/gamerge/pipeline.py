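"""End-to-end runs: load a pool, select sub-data sets, merge, report.

Three entry points mirror how the tool is used:

* :func:`run_stats` — merge everything and report the statistics table;
* :func:`run_ga` — evolutionary selection, always evaluated against the
  merge-all baseline in the same manifest;
* :func:`run_combined` — correlation clustering as a pre-selection at a
  strict cutoff, then evolutionary refinement of the surviving pool;
* :func:`run_hca` — the clustering baseline on its own.

Every run produces a manifest capturing all inputs and parameters, enough to
reproduce the run bit-identically in serial mode (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .datasets import SubDataset, read_xds_ascii, reduce_to_asu, validate_pool, write_xds_ascii
from .fitness import FitnessWeights
from .ga import GAParams, GARunRecord, GroupEvaluator, evolve
from .hca import cluster_and_cut, dendrogram_newick, pairwise_cc
from .merge import merge_group
from .scaling import scale_group
from .shells import ShellScheme, make_shells
from .stats import MergingStats, compute_stats

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_pool", "run_stats", "run_ga", "run_combined", "run_hca"]


@dataclass
class RunConfig:
    """One YAML-serialisable configuration covering all subcommands."""

    input_dir: str | None = None
    input_files: list[str] = field(default_factory=list)
    out_dir: str | None = None
    d_min: float | None = None
    d_max: float | None = None
    shell_edges: list[float] | None = None  # explicit shells override d_min/d_max
    n_shells: int = 10
    scaling_model: str = "scale"
    seed: int = 0
    ga: GAParams = field(default_factory=GAParams)
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    cc_cutoff: float = 0.95
    linkage: str = "average"
    distance: str = "one-minus-cc"
    min_cluster_size: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ga = GAParams(**raw.pop("ga", {}))
        weights = FitnessWeights(**raw.pop("weights", {}))
        return cls(ga=ga, weights=weights, **raw)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["weights"]["term_shells"] = dict(self.weights.term_shells)
        return d


def load_pool(cfg: RunConfig) -> list[SubDataset]:
    """Read, validate and reduce all sub-data sets named by the config."""
    files: list[Path] = [Path(f) for f in cfg.input_files]
    if cfg.input_dir:
        files += sorted(Path(cfg.input_dir).glob("*.HKL"))
    if len(files) < 2:
        raise ValueError(f"need at least 2 sub-data-set files, found {len(files)}")
    pool = []
    for f in files:
        try:
            pool.append(read_xds_ascii(f))
        except Exception as exc:
            raise ValueError(f"failed to load {f}: {exc}") from exc
    validate_pool(pool)
    for ds in pool:
        reduce_to_asu(ds)
    return pool


def build_shells(cfg: RunConfig, pool: Sequence[SubDataset]) -> ShellScheme:
    if cfg.shell_edges:
        return ShellScheme(tuple(cfg.shell_edges))
    d_all = np.concatenate([ds.d_spacings() for ds in pool])
    d_max = cfg.d_max if cfg.d_max is not None else float(d_all.max())
    d_min = cfg.d_min if cfg.d_min is not None else float(d_all.min())
    return make_shells(d_max, d_min, cfg.n_shells)


def _merge_and_stats(
    pool: Sequence[SubDataset],
    members: Sequence[int],
    cfg: RunConfig,
    scheme: ShellScheme,
    seed: int,
):
    group = [pool[i] for i in members]
    scales = scale_group(group, model=cfg.scaling_model)
    merged = merge_group(group, scales, rng_seed=seed)
    stats = compute_stats(merged, scheme, group[0].space_group_number)
    return merged, stats


def _manifest_base(cfg: RunConfig, pool: Sequence[SubDataset], scheme: ShellScheme) -> dict:
    return {
        "software": {"name": "gamerge", "version": __version__},
        "config": cfg.as_dict(),
        "inputs": [ds.source_path or ds.id for ds in pool],
        "n_subsets": len(pool),
        "shell_edges": list(scheme.edges),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _write_outputs(out_dir: str | Path | None, manifest: dict, extras: dict[str, str] | None = None) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for name, text in (extras or {}).items():
        (out / name).write_text(text)


def run_stats(cfg: RunConfig, pool: Sequence[SubDataset] | None = None) -> dict:
    """Merge all sub-data sets as one group and report the statistics."""
    pool = list(pool) if pool is not None else load_pool(cfg)
    scheme = build_shells(cfg, pool)
    merged, stats = _merge_and_stats(pool, range(len(pool)), cfg, scheme, cfg.seed)
    manifest = _manifest_base(cfg, pool, scheme)
    manifest["merge_all"] = {"stats": stats.as_dict(), "n_unique": merged.n_unique}
    _write_outputs(cfg.out_dir, manifest, {"stats.json": stats.to_json(indent=1), "stats.txt": stats.table()})
    return manifest


def _evolve_on(
    pool: Sequence[SubDataset], cfg: RunConfig, scheme: ShellScheme
) -> tuple[GARunRecord, GroupEvaluator]:
    evaluator = GroupEvaluator(
        pool,
        cfg.weights,
        scheme,
        scaling_model=cfg.scaling_model,
        seed=cfg.seed,
    )
    params = dataclasses.replace(cfg.ga, seed=cfg.seed)
    record = evolve(pool, params, evaluator)
    return record, evaluator


def _ga_manifest(
    cfg: RunConfig,
    pool: Sequence[SubDataset],
    scheme: ShellScheme,
    record: GARunRecord,
    evaluator: GroupEvaluator,
) -> tuple[dict, dict[str, str]]:
    # merge-all baseline: the all-in-one-group chromosome, always reported
    baseline_members = tuple(range(len(pool)))
    baseline = evaluator.score_members(baseline_members)

    best = record.best_chromosome
    best_members: list[int] = []
    best_stats: MergingStats | None = None
    if best is not None and record.best_report is not None:
        gid = record.best_report.best_group_id
        best_members = [int(i) for i in np.flatnonzero(best == gid)]
        best_score = evaluator.score_members(tuple(best_members))
        best_stats = best_score.stats

    manifest = _manifest_base(cfg, pool, scheme)
    manifest["ga"] = {
        "best_fitness": record.best_fitness,
        "best_chromosome": [int(x) for x in best] if best is not None else None,
        "best_group_members": [pool[i].id for i in best_members],
        "best_group_stats": best_stats.as_dict() if best_stats is not None else None,
        "n_evaluations": record.n_evaluations,
        "n_cache_hits": record.n_cache_hits,
        "generations": [dataclasses.asdict(g) for g in record.generations],
    }
    manifest["merge_all"] = {
        "fitness": baseline.score,
        "stats": baseline.stats.as_dict() if baseline.stats is not None else None,
    }

    extras: dict[str, str] = {}
    lines = ["generation\tbest\tmean\tbest_ever"]
    lines += [f"{g.generation}\t{g.best:.6f}\t{g.mean:.6f}\t{g.best_ever:.6f}" for g in record.generations]
    extras["generations.tsv"] = "\n".join(lines) + "\n"
    if best_stats is not None:
        extras["best_group_stats.json"] = best_stats.to_json(indent=1)
        extras["best_group_stats.txt"] = best_stats.table()
    if best_members and cfg.out_dir is not None:
        Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
        group = [pool[i] for i in best_members]
        scales = scale_group(group, model=cfg.scaling_model)
        merged = merge_group(group, scales, rng_seed=evaluator._half_split_seed(tuple(sorted(best_members))))
        out_ds = SubDataset(
            id="best_group_merged",
            cell=group[0].cell,
            space_group_number=group[0].space_group_number,
            friedel_law=group[0].friedel_law,
            hkl=merged.hkl,
            intensity=merged.mean_I,
            sigma=merged.sigma_mean,
        )
        write_xds_ascii(out_ds, Path(cfg.out_dir) / "best_group_merged.HKL")
    return manifest, extras


def run_ga(cfg: RunConfig, pool: Sequence[SubDataset] | None = None) -> dict:
    """Evolutionary selection of merging groups over the full pool."""
    pool = list(pool) if pool is not None else load_pool(cfg)
    scheme = build_shells(cfg, pool)
    t0 = time.perf_counter()
    record, evaluator = _evolve_on(pool, cfg, scheme)
    manifest, extras = _ga_manifest(cfg, pool, scheme, record, evaluator)
    manifest["runtime_s"] = round(time.perf_counter() - t0, 3)
    _write_outputs(cfg.out_dir, manifest, extras)
    return manifest


def run_hca(cfg: RunConfig, pool: Sequence[SubDataset] | None = None) -> dict:
    """Clustering baseline: cut the CC dendrogram, merge the largest cluster."""
    pool = list(pool) if pool is not None else load_pool(cfg)
    scheme = build_shells(cfg, pool)
    dm = pairwise_cc(pool, distance=cfg.distance)
    clusters = cluster_and_cut(dm, cfg.cc_cutoff, linkage=cfg.linkage)
    top = clusters[0]
    manifest = _manifest_base(cfg, pool, scheme)
    manifest["hca"] = {
        "cc_cutoff": cfg.cc_cutoff,
        "linkage": cfg.linkage,
        "clusters": [[pool[i].id for i in c] for c in clusters],
        "selected": [pool[i].id for i in top],
    }
    extras = {"dendrogram.nwk": dendrogram_newick(dm, linkage=cfg.linkage) + "\n"}
    lines = ["subset\tcluster"]
    for rank, c in enumerate(clusters):
        lines += [f"{pool[i].id}\t{rank}" for i in c]
    extras["clusters.tsv"] = "\n".join(lines) + "\n"
    if len(top) >= 1:
        _, stats = _merge_and_stats(pool, top, cfg, scheme, cfg.seed)
        manifest["hca"]["selected_stats"] = stats.as_dict()
        extras["selected_stats.json"] = stats.to_json(indent=1)
    _write_outputs(cfg.out_dir, manifest, extras)
    return manifest


def run_combined(cfg: RunConfig, pool: Sequence[SubDataset] | None = None) -> dict:
    """Strict-cutoff cluster pre-selection followed by evolutionary refinement."""
    pool = list(pool) if pool is not None else load_pool(cfg)
    scheme = build_shells(cfg, pool)
    t0 = time.perf_counter()
    dm = pairwise_cc(pool, distance=cfg.distance)
    clusters = cluster_and_cut(dm, cfg.cc_cutoff, linkage=cfg.linkage)
    selected = sorted(clusters[0])
    fallback = False
    if len(selected) < 2:
        logger.warning("pre-selection left %d subset(s); falling back to the full pool", len(selected))
        selected = list(range(len(pool)))
        fallback = True
    sub_pool = [pool[i] for i in selected]
    record, evaluator = _evolve_on(sub_pool, cfg, scheme)
    manifest, extras = _ga_manifest(cfg, sub_pool, scheme, record, evaluator)
    manifest["preselection"] = {
        "cc_cutoff": cfg.cc_cutoff,
        "clusters": [[pool[i].id for i in c] for c in clusters],
        "selected": [pool[i].id for i in selected],
        "fallback_full_pool": fallback,
    }
    manifest["runtime_s"] = round(time.perf_counter() - t0, 3)
    _write_outputs(cfg.out_dir, manifest, extras)
    return manifest
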