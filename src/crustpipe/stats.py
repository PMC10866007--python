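"""Group-comparison statistics shared across the pipeline.

One-way ANOVA with Tukey HSD post hoc (soil chemistry, enzyme activities,
alpha diversity), Kruskal-Wallis with pairwise rank-sum tests for taxon
relative abundances, Benjamini-Hochberg FDR adjustment, significance
stars and compact letter displays (groups sharing a letter do not differ
at the chosen alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DEFAULT_STAR_MAP = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class InferenceError(ValueError):
    pass


def stars(p: float, star_map=DEFAULT_STAR_MAP) -> str:
    """Significance stars for a p value (ns below the loosest level)."""
    for level, symbol in sorted(star_map):
        if p < level:
            return symbol
    return "ns"


@dataclass
class GroupComparisonResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, estimate, p, p_adj, stars
    letters: dict[str, str] = field(default_factory=dict)


def _split_groups(values, groups, min_size: int = 2):
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups)})
    if df["value"].isna().any():
        raise InferenceError("values contain NaN")
    parts = {g: sub["value"].to_numpy() for g, sub in df.groupby("group", sort=True)}
    if len(parts) < 2:
        raise InferenceError("need at least two groups")
    for g, v in parts.items():
        if v.size < min_size:
            raise InferenceError(f"group {g!r} has fewer than {min_size} values")
    return parts


def one_way_anova(values, groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p.

    Degenerate complete separation (zero within-group variance with
    differing means) is reported as F = inf, p = 0.
    """
    parts = _split_groups(values, groups)
    arrays = list(parts.values())
    if np.var(np.concatenate(arrays)) == 0:
        raise InferenceError("zero total variance: ANOVA undefined")
    within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if within == 0:
        return float("inf"), 0.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InferenceError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compact_letter_display(
    groups: list[str],
    significant: dict[frozenset, bool],
    means: dict[str, float],
) -> dict[str, str]:
    """Compact letter display via insert-and-absorb.

    Starts from one letter covering all groups; every significantly
    different pair splits each letter containing both; letters that
    become subsets of another are absorbed.  Letters are assigned a..z in
    order of descending group mean, so 'a' marks the highest group.
    """
    order = sorted(groups, key=lambda g: (-means[g], g))
    letters: list[set[str]] = [set(order)]
    for pair, sig in significant.items():
        if not sig:
            continue
        g1, g2 = sorted(pair)
        for s in [s for s in letters if g1 in s and g2 in s]:
            letters.remove(s)
            a, b = s - {g1}, s - {g2}
            for new in (a, b):
                if not any(new <= other for other in letters):
                    letters.append(new)
    # absorb (defensive; insertion already checks)
    letters = [s for s in letters if not any(s < o for o in letters)]
    # order letters by the highest-mean group they contain
    rank = {g: i for i, g in enumerate(order)}
    letters.sort(key=lambda s: min(rank[g] for g in s))
    out = {g: "" for g in groups}
    for i, s in enumerate(letters):
        ch = chr(ord("a") + i)
        for g in s:
            out[g] += ch
    return {g: "".join(sorted(v)) for g, v in out.items()}


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons with a compact letter display.

    Returns a frame (group_a, group_b, estimate, p, stars) whose
    ``attrs["letters"]`` maps each group to its letters at ``alpha``.
    """
    parts = _split_groups(values, groups)
    names = list(parts.keys())
    res = sps.tukey_hsd(*[parts[g] for g in names])
    rows = []
    sig: dict[frozenset, bool] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res.pvalue[i, j])
            est = float(parts[names[i]].mean() - parts[names[j]].mean())
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "estimate": est,
                    "p": p,
                    "stars": stars(p),
                }
            )
            sig[frozenset({names[i], names[j]})] = p < alpha
    table = pd.DataFrame(rows)
    means = {g: float(v.mean()) for g, v in parts.items()}
    table.attrs["letters"] = compact_letter_display(names, sig, means)
    return table


def kruskal_wallis_with_pairwise(
    values, groups, variable: str = ""
) -> GroupComparisonResult:
    """Kruskal-Wallis H (tie-corrected) with pairwise rank-sum tests.

    Pairwise two-sided Mann-Whitney p values are BH-FDR adjusted across
    the pairs of one variable.  All-tied data yields H = 0, p = 1.
    """
    parts = _split_groups(values, groups)
    names = list(parts.keys())
    allv = np.concatenate(list(parts.values()))
    if np.all(allv == allv[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*[parts[g] for g in names])
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = parts[names[i]], parts[names[j]]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                pij, est = 1.0, 0.0
            else:
                pij = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                est = float(np.median(a) - np.median(b))
            rows.append(
                {"group_a": names[i], "group_b": names[j], "estimate": est, "p": pij}
            )
    pw = pd.DataFrame(rows)
    pw["p_adj"] = bh_fdr(pw["p"]) if len(pw) else []
    pw["stars"] = [stars(x) for x in pw["p_adj"]]
    sig = {
        frozenset({r.group_a, r.group_b}): r.p_adj < 0.05 for r in pw.itertuples()
    }
    medians = {g: float(np.median(v)) for g, v in parts.items()}
    return GroupComparisonResult(
        variable=variable,
        test="kruskal-wallis",
        statistic=float(h),
        p_value=float(p),
        pairwise=pw,
        letters=compact_letter_display(names, sig, medians),
    )
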