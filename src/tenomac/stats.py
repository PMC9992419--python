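"""Statistical test battery shared across quantification stages.

Group comparisons of percentages, densities, and depth-enrichment
ratios use one-way ANOVA with Tukey's post-hoc test, preceded by
Shapiro-Wilk normality and Levene homogeneity checks; paired fractions
use the paired t-test; expression contrasts use the exact two-sided
Mann-Whitney U test.  Alpha is 0.05 throughout.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

ALPHA = 0.05

__all__ = ["compare_groups", "paired_t_report", "mannwhitney_exact", "ALPHA"]


def compare_groups(values: dict[str, list[float]],
                   alpha: float = ALPHA) -> dict:
    """One-way ANOVA + Tukey HSD with normality/variance preflight.

    Parameters
    ----------
    values
        Mapping group name -> per-animal means (>= 2 groups of >= 2).

    Returns
    -------
    dict with per-group Shapiro-Wilk p, Levene p, ANOVA F and p, and all
    pairwise Tukey adjusted p-values.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, g in groups.items():
        if g.size < 2:
            raise ValueError(f"group {name!r} has < 2 values")

    shapiro = {}
    for name, g in groups.items():
        if np.ptp(g) == 0:
            shapiro[name] = np.nan      # degenerate: identical values
        else:
            shapiro[name] = float(stats.shapiro(g).pvalue)
    arrays = list(groups.values())
    names = list(groups)
    try:
        levene_p = float(stats.levene(*arrays).pvalue)
    except Exception:
        levene_p = np.nan
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: no effect, define F = 0, p = 1
        anova_F, anova_p = 0.0, 1.0
    else:
        anova = stats.f_oneway(*arrays)
        anova_F, anova_p = float(anova.statistic), float(anova.pvalue)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = {
        f"{names[i]} vs {names[j]}": float(tukey.pvalue[i, j])
        for i, j in combinations(range(len(names)), 2)
    }
    return {
        "alpha": alpha,
        "groups": {k: {"n": int(g.size), "mean": float(g.mean()),
                       "sd": float(g.std(ddof=1))}
                   for k, g in groups.items()},
        "shapiro_p": shapiro,
        "levene_p": levene_p,
        "anova_F": anova_F,
        "anova_p": anova_p,
        "tukey_p": pairwise,
    }


def paired_t_report(a, b) -> dict:
    """Paired t-test report (t, df, p) for matched per-animal fractions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need >= 2 complete pairs")
    diff = a - b
    if np.ptp(diff) == 0 and diff[0] == 0:
        return {"t": 0.0, "df": int(a.size - 1), "p": 1.0}
    res = stats.ttest_rel(a, b)
    return {"t": float(res.statistic), "df": int(a.size - 1),
            "p": float(res.pvalue)}


def mannwhitney_exact(a, b) -> dict:
    """Two-sided Mann-Whitney U with the exact null distribution."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    return {"U": float(res.statistic), "p": float(res.pvalue)}
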