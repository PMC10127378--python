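"""The nonparametric statistical battery used for group comparisons.

Small-group electrophysiology calls for rank-based tests: Kruskal-Wallis
omnibus with Dunn's pairwise z comparisons (Holm-adjusted; unadjusted
values also reported), Wilcoxon signed-rank for paired designs (exact null
distribution for n <= 25), Mann-Whitney U, two-sample Kolmogorov-Smirnov
for pooled event distributions, and a two-way ANOVA (condition x stimulus
strength) for input-output families with Sidak-adjusted per-strength
follow-ups.  Scipy/statsmodels provide the numerics behind each contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class StatResult:
    """A single test outcome with optional post-hoc comparisons."""

    test: str
    statistic: float
    p: float
    group_sizes: list = field(default_factory=list)
    df: float | None = None
    posthoc: list = field(default_factory=list)  # (pair, p_adjusted)
    posthoc_unadjusted: list = field(default_factory=list)
    alpha: float = ALPHA
    flag: str = ""

    @property
    def significant(self) -> bool:
        return self.p <= self.alpha


def _check_groups(groups: list, min_groups: int, min_n: int) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group passed to a rank test")
    if any(a.size < min_n for a in arrs):
        raise ValueError(f"each group needs at least {min_n} observations")
    return arrs


def kruskal_dunn(groups: list, labels: list[str] | None = None,
                 adjust: str = "holm", include_posthoc: bool = True) -> StatResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise comparisons.

    Dunn's z statistics compare mean ranks of the pooled sample with the
    tie-corrected standard error; pairwise p values are Holm-adjusted
    across all pairs (unadjusted values are also reported).
    ``include_posthoc=False`` skips the pairwise stage (useful when only
    the omnibus decision is needed, e.g. in resampling loops).
    """
    arrs = _check_groups(groups, 3, 3)
    labels = labels or [f"group{i}" for i in range(len(arrs))]
    h, p = sps.kruskal(*arrs)
    if not include_posthoc:
        return StatResult(test="kruskal-wallis", statistic=float(h), p=float(p),
                          group_sizes=[a.size for a in arrs], df=len(arrs) - 1)

    pooled = np.concatenate(arrs)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    sizes = [a.size for a in arrs]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(float(np.mean(ranks[start:start + s])))
        start += s
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs, praw = [], []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((labels[i], labels[j]))
            praw.append(2.0 * sps.norm.sf(abs(z)))
    adj = multipletests(praw, method=adjust)[1] if praw else []
    return StatResult(test="kruskal-wallis", statistic=float(h), p=float(p),
                      group_sizes=sizes, df=len(arrs) - 1,
                      posthoc=list(zip(pairs, map(float, adj))),
                      posthoc_unadjusted=list(zip(pairs, map(float, praw))))


def paired_wilcoxon(before, after) -> StatResult:
    """Wilcoxon signed-rank test for paired observations.

    The reported W is the signed rank sum (positive-rank sum minus
    negative-rank sum), so swapping the arguments negates W and leaves p
    unchanged.  The exact null distribution is used for n <= 25; all-zero
    differences degenerate (flagged, p = nan).
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.size != a.size:
        raise ValueError("paired samples must have equal length")
    if b.size < 6:
        raise ValueError("need at least 6 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return StatResult(test="wilcoxon", statistic=np.nan, p=np.nan,
                          group_sizes=[b.size], flag="degenerate: all differences zero")
    ranks = sps.rankdata(np.abs(d))
    w_signed = float(np.sum(ranks[d > 0]) - np.sum(ranks[d < 0]))
    method = "exact" if d.size <= 25 else "approx"
    res = sps.wilcoxon(d, method=method)
    return StatResult(test="wilcoxon", statistic=w_signed, p=float(res.pvalue),
                      group_sizes=[int(d.size)])


def mann_whitney(a, b) -> StatResult:
    """Two-sample Mann-Whitney U test (two-sided)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return StatResult(test="mann-whitney", statistic=float(res.statistic),
                      p=float(res.pvalue), group_sizes=[a.size, b.size])


def ks_two_sample(pooled_a, pooled_b) -> StatResult:
    """Two-sample Kolmogorov-Smirnov test on pooled event distributions."""
    a = np.asarray(pooled_a, dtype=float)
    b = np.asarray(pooled_b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ValueError("KS test needs >= 10 observations per sample")
    res = sps.ks_2samp(a, b, method="asymp")
    return StatResult(test="kolmogorov-smirnov", statistic=float(res.statistic),
                      p=float(res.pvalue), group_sizes=[a.size, b.size])


def two_way_anova_io(curves: dict[str, list[pd.DataFrame]],
                     value: str = "fepsp_slope") -> StatResult:
    """Two-way ANOVA (condition x stimulus strength) over IO curves.

    ``curves`` maps condition label -> list of per-slice IO DataFrames
    (columns ``stimulus`` and ``value``).  Returns the condition main
    effect with Sidak-adjusted per-strength pairwise t-test follow-ups.
    Empty design cells raise with the offending cells listed.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rows = []
    for cond, dfs in curves.items():
        for i, df in enumerate(dfs):
            for _, r in df.iterrows():
                rows.append({"condition": cond, "strength": float(r["stimulus"]),
                             "y": float(r[value]), "slice": f"{cond}_{i}"})
    data = pd.DataFrame(rows)
    cells = data.groupby(["condition", "strength"]).size()
    all_conditions = list(curves)
    all_strengths = sorted(data["strength"].unique())
    missing = [(c, s) for c in all_conditions for s in all_strengths
               if (c, s) not in cells.index]
    if missing:
        raise ValueError(f"empty design cells: {missing}")

    model = smf.ols("y ~ C(condition) * C(strength)", data=data).fit()
    table = anova_lm(model, typ=2)
    f = float(table.loc["C(condition)", "F"])
    p = float(table.loc["C(condition)", "PR(>F)"])
    df_cond = float(table.loc["C(condition)", "df"])

    pairs, praw = [], []
    for s in all_strengths:
        sub = data[data["strength"] == s]
        for i in range(len(all_conditions)):
            for j in range(i + 1, len(all_conditions)):
                x = sub[sub.condition == all_conditions[i]]["y"]
                y = sub[sub.condition == all_conditions[j]]["y"]
                if len(x) < 2 or len(y) < 2:
                    continue
                t = sps.ttest_ind(x, y)
                pairs.append((f"{all_conditions[i]} vs {all_conditions[j]} @ {s:g}", ))
                praw.append(float(t.pvalue))
    adj = multipletests(praw, method="sidak")[1] if praw else []
    return StatResult(test="two-way-anova", statistic=f, p=p, df=df_cond,
                      group_sizes=[len(dfs) for dfs in curves.values()],
                      posthoc=list(zip([p0[0] for p0 in pairs], map(float, adj))),
                      posthoc_unadjusted=list(zip([p0[0] for p0 in pairs],
                                                  map(float, praw))))
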