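"""Group statistics for quantified imaging and flow readouts.

Mirrors the statistical conventions of the source workflow: two groups
are compared with the Mann-Whitney U test (exact two-sided p for small
tie-free samples, normal approximation with tie correction otherwise);
three or more groups use one-way ANOVA followed by Tukey's HSD for all
pairwise comparisons; outliers deviating more than two sample standard
deviations from the group mean are removed in a single pass; summaries
are mean ± SEM; significance stars use the usual cutpoints
(* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001, strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

#: Product-of-sample-sizes bound below which the exact U distribution
#: is used (tie-free data only).
EXACT_U_LIMIT = 200

_STAR_CUTPOINTS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"),
                   (0.05, "*"))


@dataclass
class ComparisonResult:
    """One hypothesis-test row."""

    test: str                      # e.g. "mann-whitney-exact", "anova", "tukey"
    statistic: float
    p_value: float
    groups: tuple[str, ...] = ()
    significance: str = "ns"
    degenerate: bool = False
    note: str = ""


def significance_code(p: float) -> str:
    """Star notation with strict inequalities at 0.05/0.01/0.001/0.0001."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    for cut, stars in _STAR_CUTPOINTS:
        if p < cut:
            return stars
    return "ns"


def remove_outliers_2sd(values) -> tuple[list[float], list[float]]:
    """Single-pass 2-SD outlier rule.

    Mean and sample SD are computed once on the full group; values with
    |x - mean| > 2*SD are removed.  The rule is not re-applied to the
    retained set.  Constant groups (SD = 0) lose nothing.
    """
    arr = np.asarray(list(values), float)
    if arr.size < 2:
        raise ValueError("need at least two values for the outlier rule")
    mean = arr.mean()
    sd = arr.std(ddof=1)
    keep = np.abs(arr - mean) <= 2 * sd
    return arr[keep].tolist(), arr[~keep].tolist()


def mann_whitney(a, b, labels: tuple[str, str] = ("a", "b")
                 ) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution of U when n*m <= 200 and there are
    no ties across the pooled sample; otherwise the normal approximation
    with midrank tie correction and continuity correction.  The result's
    `test` field records which path ran.
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    exact = tie_free and a.size * b.size <= EXACT_U_LIMIT
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(1.0, res.pvalue))
    return ComparisonResult(
        test=f"mann-whitney-{method}",
        statistic=float(res.statistic),
        p_value=p,
        groups=labels,
        significance=significance_code(p),
    )


def anova_tukey(groups: dict[str, list[float]],
                alpha: float = 0.05) -> list[ComparisonResult]:
    """One-way ANOVA followed by Tukey HSD on all pairs.

    Returns the ANOVA row first, then one Tukey row per pair (all pairs
    are reported regardless of the ANOVA outcome).  When every group has
    exactly zero within-group variance but the means differ, F is
    undefined; a flagged degenerate result is returned instead of a
    crash.
    """
    if len(groups) < 3:
        raise ValueError("anova_tukey needs >= 3 groups; use mann_whitney "
                         "for two")
    arrays = {k: np.asarray(list(v), float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    labels = list(arrays)
    within_var = sum(float(((v - v.mean()) ** 2).sum()) for v in arrays.values())
    means = [v.mean() for v in arrays.values()]
    if within_var == 0.0:
        if np.ptp(means) == 0:
            # all values identical everywhere: no difference at all
            rows = [ComparisonResult("anova", 0.0, 1.0, tuple(labels))]
            rows += [ComparisonResult("tukey", 0.0, 1.0, (labels[i], labels[j]))
                     for i in range(len(labels))
                     for j in range(i + 1, len(labels))]
            return rows
        return [ComparisonResult(
            "anova", float("nan"), float("nan"), tuple(labels),
            significance="ns", degenerate=True,
            note="zero within-group variance with unequal means; "
                 "F undefined")]
    f, p = sps.f_oneway(*arrays.values())
    p = float(p)
    rows = [ComparisonResult("anova", float(f), p, tuple(labels),
                             significance=significance_code(p))]
    values = np.concatenate(list(arrays.values()))
    codes = np.concatenate([[k] * arrays[k].size for k in labels])
    tukey = pairwise_tukeyhsd(values, codes, alpha=alpha)
    pairs = list(combinations(tukey.groupsunique, 2))
    for (g1, g2), stat, adj_p in zip(pairs, tukey.meandiffs, tukey.pvalues):
        adj_p = float(adj_p)
        rows.append(ComparisonResult(
            "tukey", float(stat), adj_p, (str(g1), str(g2)),
            significance=significance_code(adj_p)))
    return rows


def summarize(groups: dict[str, list[float]]) -> list[dict]:
    """Mean ± SEM (sample SD / sqrt(n)) per group; SEM is blank (NaN)
    for n = 1."""
    rows = []
    for label, values in groups.items():
        arr = np.asarray(list(values), float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 \
            else float("nan")
        rows.append({"group": label, "mean": float(arr.mean()),
                     "sem": sem, "n": int(arr.size)})
    return rows


def compare_groups(groups: dict[str, list[float]],
                   exclude_outliers: bool = True) -> dict:
    """Route groups through the declared decision rule.

    Optionally applies the 2-SD rule per group, then Mann-Whitney for
    two groups or ANOVA + Tukey for three or more.  Returns the summary
    rows, the comparison rows, and what was removed.
    """
    cleaned: dict[str, list[float]] = {}
    removed: dict[str, list[float]] = {}
    for label, values in groups.items():
        vals = list(values)
        if exclude_outliers and len(vals) >= 2:
            vals, out = remove_outliers_2sd(vals)
            removed[label] = out
        else:
            removed[label] = []
        cleaned[label] = vals
    if len(cleaned) == 2:
        (la, a), (lb, b) = cleaned.items()
        comparisons = [mann_whitney(a, b, labels=(la, lb))]
    else:
        comparisons = anova_tukey(cleaned)
    return {
        "summary": summarize(cleaned),
        "comparisons": comparisons,
        "outliers_removed": removed,
    }


def comparisons_table(comparisons: list[ComparisonResult]) -> list[dict]:
    """Flatten comparison rows for the stats CSV."""
    return [{
        "test": c.test,
        "groups": "|".join(c.groups),
        "statistic": c.statistic,
        "p_value": c.p_value,
        "significance": c.significance,
        "degenerate": c.degenerate,
        "note": c.note,
    } for c in comparisons]
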