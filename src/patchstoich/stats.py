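"""Nonparametric two-sample comparisons with the study's testing policy.

The Brunner-Munzel test compares two samples through the relative effect
p = P(X < Y) + 0.5 P(X = Y): under stochastic equality p = 1/2.  Midranks
handle ties; the studentized statistic is referred to a t distribution with
Welch-type degrees of freedom (or, for small samples, to the exact
distribution over all group relabelings).  Families of tests use a Bonferroni
adjusted level (0.05 / 5 = 0.01 for the five planned comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import DegenerateSamplesError, ParameterError

__all__ = ["ComparisonResult", "brunner_munzel", "bonferroni_alpha",
           "compare_conditions"]


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    n_x: int
    n_y: int
    relative_effect: float      # P(X < Y) + 0.5 P(X = Y)
    significant: bool | None = None
    alpha: float | None = None
    method: str = "t"


def _relative_effect(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    ry = ranks[len(x):]
    return float((ry.mean() - (len(y) + 1) / 2.0) / len(x))


def _bm_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Studentized Brunner-Munzel statistic (nan if the rank variance is 0)."""
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx, ry = ranks[:nx], ranks[nx:]
    rx_in = sps.rankdata(x)
    ry_in = sps.rankdata(y)
    sx2 = np.sum((rx - rx_in - rx.mean() + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((ry - ry_in - ry.mean() + (ny + 1) / 2.0) ** 2) / (ny - 1)
    sigma2 = nx * sx2 + ny * sy2
    if sigma2 == 0:
        return float("nan")
    return float((ry.mean() - rx.mean()) * np.sqrt(nx * ny)
                 / np.sqrt((nx + ny) * sigma2))


def brunner_munzel(x, y, alternative: str = "two-sided",
                   method: str = "t") -> ComparisonResult:
    """Brunner-Munzel test of stochastic equality of two samples.

    ``method="t"`` uses the t reference distribution with Welch-type degrees
    of freedom (via scipy); ``method="exact"`` enumerates the studentized
    statistic over all group relabelings of the pooled sample (feasible for
    small n) and reports the two-sided permutation p value.  All-tied or
    completely separated samples have zero rank variance and raise
    :class:`DegenerateSamplesError`.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each sample needs >= 2 observations")
    effect = _relative_effect(x, y)

    if method == "t":
        with np.errstate(divide="ignore", invalid="ignore"):
            stat, p = sps.brunnermunzel(x, y, alternative=alternative,
                                        distribution="t")
        if not np.isfinite(p):
            raise DegenerateSamplesError(
                "zero rank variance (all ties or complete separation); "
                "the Brunner-Munzel statistic is undefined")
        return ComparisonResult(float(stat), float(p), len(x), len(y),
                                effect, method="t")

    if method == "exact":
        t_obs = _bm_statistic(x, y)
        if np.isnan(t_obs):
            raise DegenerateSamplesError(
                "zero rank variance (all ties or complete separation); "
                "the Brunner-Munzel statistic is undefined")
        pooled = np.concatenate([x, y])
        n, nx = len(pooled), len(x)
        idx = np.arange(n)
        count = total = 0
        for comb in combinations(idx, nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(comb)] = True
            t_perm = _bm_statistic(pooled[mask], pooled[~mask])
            if np.isnan(t_perm):
                t_perm = np.inf  # separation is as extreme as it gets
            total += 1
            if abs(t_perm) >= abs(t_obs) - 1e-12:
                count += 1
        return ComparisonResult(t_obs, count / total, len(x), len(y),
                                effect, method="exact")

    raise ParameterError(f"unknown method {method!r}")


def bonferroni_alpha(family_alpha: float = 0.05, n_tests: int = 5) -> float:
    """Bonferroni-adjusted per-test significance level family_alpha / n."""
    if n_tests < 1:
        raise ParameterError("n_tests must be >= 1")
    if not 0 < family_alpha <= 1:
        raise ParameterError("family_alpha must be in (0, 1]")
    return family_alpha / n_tests


def _summary(v: np.ndarray) -> dict:
    v = np.asarray(v, dtype=float)
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
    }


def compare_conditions(
    condition_a: dict,
    condition_b: dict,
    split: float = 15.0,
    family_alpha: float = 0.05,
    n_tests: int = 5,
) -> dict:
    """Between-condition comparison report.

    Each condition is ``{"tracks_per_cell": [...], "stoichiometries": [...]}``.
    Runs Brunner-Munzel on (a) per-cell track counts, (b) pooled
    stoichiometries, and (c) the sub-populations below/above the stoichiometry
    split (S < split and S >= split, so every value lands in exactly one
    subgroup), flagging significance at the Bonferroni-adjusted level.
    """
    alpha = bonferroni_alpha(family_alpha, n_tests)
    sa = np.asarray(condition_a["stoichiometries"], dtype=float)
    sb = np.asarray(condition_b["stoichiometries"], dtype=float)
    if sa.size == 0 or sb.size == 0:
        raise ParameterError("both conditions need stoichiometries")

    report: dict = {"adjusted_alpha": alpha, "split": split, "tests": {}}

    def run(name: str, x: np.ndarray, y: np.ndarray) -> None:
        entry: dict = {"group_a": _summary(x), "group_b": _summary(y)}
        try:
            res = brunner_munzel(x, y)
            res.alpha = alpha
            res.significant = res.p_value < alpha
            entry.update(statistic=res.statistic, p_value=res.p_value,
                         relative_effect=res.relative_effect,
                         significant=res.significant,
                         n=res.n_x + res.n_y)
        except (DegenerateSamplesError, ParameterError) as exc:
            entry["error"] = str(exc)
        report["tests"][name] = entry

    ta = np.asarray(condition_a.get("tracks_per_cell", []), dtype=float)
    tb = np.asarray(condition_b.get("tracks_per_cell", []), dtype=float)
    if ta.size and tb.size:
        run("tracks_per_cell", ta, tb)
    run("stoichiometry", sa, sb)
    run("stoichiometry_below_split", sa[sa < split], sb[sb < split])
    run("stoichiometry_above_split", sa[sa >= split], sb[sb >= split])
    return report
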