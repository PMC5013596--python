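"""Scalar fitness from merging statistics.

A merging group's score is a weighted sum of data-quality terms; since the
optimiser maximises, every term is oriented so that higher is better.  By
default the terms use the shells where each statistic is most informative:
R_meas and <I/sigma(I)> from the inner (low-resolution) shell, CC1/2 from
the outer shell, completeness and multiplicity overall.  R_meas, a
lower-is-better quantity, is transformed to 100 - R_meas (default) or
1/R_meas.

An optional anomalous-signal term is either the inner-shell SigAno or an
anomalous-resolution score 10/d*, where d* is the finest resolution down to
which SigAno stays above 1.0 and CC_anom above 30%.

An individual's fitness is the best group score, or the mean over non-empty
groups when segregating several non-isomorphous groups at once is the goal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .stats import MergingStats, ShellStats

__all__ = ["FitnessWeights", "GroupScore", "FitnessReport", "score_group", "score_individual"]

MIN_FITNESS = -1.0e9  # sentinel for empty / unevaluable individuals
RECIPROCAL_CEILING = 1.0e4

_SHELL_CHOICES = ("inner", "outer", "overall")


@dataclass(frozen=True)
class FitnessWeights:
    """Term weights and scoring modes.

    ``term_shells`` may override which shell each statistic is read from
    (keys: r, i, cc, comp, mult, ano; values: inner/outer/overall).
    """

    w_r: float = 1.0
    w_i: float = 1.0
    w_cc: float = 1.0
    w_comp: float = 1.0
    w_mult: float = 1.0
    w_ano: float = 0.0
    r_transform: str = "subtract"  # or "reciprocal"
    ano_mode: str = "off"  # "sigano" or "resolution"
    score_mode: str = "best"  # or "combined"
    # I/sigma source for the fitness term: the per-observation mean
    # ("observations", default) is flat in multiplicity, so the term compares
    # signal quality rather than sheer data quantity; "merged" uses the
    # error-propagated merged ratio, which grows like sqrt(multiplicity)
    i_source: str = "observations"
    term_shells: Mapping[str, str] = field(
        default_factory=lambda: {
            "r": "inner",
            "i": "inner",
            "cc": "outer",
            "comp": "overall",
            "mult": "overall",
            "ano": "inner",
        }
    )

    def __post_init__(self) -> None:
        weights = (self.w_r, self.w_i, self.w_cc, self.w_comp, self.w_mult, self.w_ano)
        if any(w < 0 for w in weights):
            raise ValueError("weights must be non-negative")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one weight must be positive")
        if self.r_transform not in ("subtract", "reciprocal"):
            raise ValueError(f"unknown r_transform {self.r_transform!r}")
        if self.ano_mode not in ("off", "sigano", "resolution"):
            raise ValueError(f"unknown ano_mode {self.ano_mode!r}")
        if self.score_mode not in ("best", "combined"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        if self.i_source not in ("observations", "merged"):
            raise ValueError(f"unknown i_source {self.i_source!r}")
        for key, shell in self.term_shells.items():
            if shell not in _SHELL_CHOICES:
                raise ValueError(f"term_shells[{key!r}] must be one of {_SHELL_CHOICES}")


@dataclass
class GroupScore:
    group_id: int
    score: float
    terms: dict = field(default_factory=dict)  # term -> raw statistic value
    contributions: dict = field(default_factory=dict)  # term -> weight * transformed
    empty: bool = False
    stats: MergingStats | None = None  # attached by the evaluator for reporting


@dataclass
class FitnessReport:
    """Per-group scores and the resulting fitness of one individual."""

    groups: list[GroupScore]
    fitness: float
    best_group_id: int


def _shell_of(stats: MergingStats, which: str) -> ShellStats:
    return {"inner": stats.inner, "outer": stats.outer, "overall": stats.overall}[which]


def _transform_r(r_meas: float | None, transform: str) -> float:
    # undefined R scores as the worst representable value of its transform
    if transform == "subtract":
        return 100.0 - (100.0 if r_meas is None else r_meas)
    if r_meas is None:
        return 1.0 / 100.0
    if r_meas <= 0:
        return RECIPROCAL_CEILING
    return min(1.0 / r_meas, RECIPROCAL_CEILING)


def _anomalous_resolution_score(stats: MergingStats) -> float:
    """10/d* with d* the finest d kept while SigAno > 1 and CC_anom > 30%.

    The contiguous run of shells starting at the inner shell is scanned; if
    the inner shell itself fails, the term scores 0 (worst).
    """
    d_star = None
    for shell in stats.shells:
        if shell.sig_ano is not None and shell.sig_ano > 1.0 and shell.cc_anom is not None and shell.cc_anom > 30.0:
            d_star = shell.d_min
        else:
            break
    return 0.0 if d_star is None else 10.0 / d_star


def score_group(stats: MergingStats | None, weights: FitnessWeights, group_id: int = 0) -> GroupScore:
    """Score one merging group; ``stats=None`` denotes an empty group."""
    if stats is None:
        return GroupScore(group_id=group_id, score=MIN_FITNESS, empty=True)
    sh = weights.term_shells
    r_val = _shell_of(stats, sh["r"]).r_meas
    i_shell = _shell_of(stats, sh["i"])
    i_val = i_shell.mean_i_over_sigma_obs if weights.i_source == "observations" else i_shell.mean_i_over_sigma
    cc_val = _shell_of(stats, sh["cc"]).cc_half
    comp_val = stats.overall.completeness if sh["comp"] == "overall" else _shell_of(stats, sh["comp"]).completeness
    mult_val = _shell_of(stats, sh["mult"]).multiplicity

    terms: dict[str, float | None] = {
        "r_meas": r_val,
        "i_over_sigma": i_val,
        "cc_half": cc_val,
        "completeness": comp_val,
        "multiplicity": mult_val,
    }
    contributions = {
        "r_meas": weights.w_r * _transform_r(r_val, weights.r_transform),
        "i_over_sigma": weights.w_i * (i_val if i_val is not None else 0.0),
        "cc_half": weights.w_cc * (cc_val if cc_val is not None else 0.0),
        "completeness": weights.w_comp * (comp_val if comp_val is not None else 0.0),
        "multiplicity": weights.w_mult * (mult_val if mult_val is not None else 0.0),
    }
    if weights.ano_mode == "sigano":
        a_val = _shell_of(stats, sh["ano"]).sig_ano
        terms["anomalous"] = a_val
        contributions["anomalous"] = weights.w_ano * (a_val if a_val is not None else 0.0)
    elif weights.ano_mode == "resolution":
        a_val = _anomalous_resolution_score(stats)
        terms["anomalous"] = a_val
        contributions["anomalous"] = weights.w_ano * a_val
    score = float(sum(contributions.values()))
    return GroupScore(group_id=group_id, score=score, terms=terms, contributions=contributions)


def score_individual(groups: Sequence[GroupScore], weights: FitnessWeights) -> FitnessReport:
    """Fitness of one individual from its group scores.

    best mode: the maximum group score (ties broken by lowest group id);
    combined mode: the mean over non-empty groups.  All-empty individuals
    receive the minimal sentinel so they survive but are dominated.
    """
    if not groups:
        raise ValueError("no groups to score")
    non_empty = [g for g in groups if not g.empty]
    if not non_empty:
        return FitnessReport(groups=list(groups), fitness=MIN_FITNESS, best_group_id=groups[0].group_id)
    best = min(non_empty, key=lambda g: (-g.score, g.group_id))
    if weights.score_mode == "best":
        fitness = best.score
    else:
        fitness = float(sum(g.score for g in non_empty) / len(non_empty))
    return FitnessReport(groups=list(groups), fitness=fitness, best_group_id=best.group_id)
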