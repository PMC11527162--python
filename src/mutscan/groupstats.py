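"""Strain-comparison statistics with normality-gated test selection and a
compact letter display.

Replicate uptake rates per strain are compared by one-way ANOVA with
Tukey HSD post-hoc when Shapiro-Wilk on the model residuals does not
reject normality (p >= 0.05); otherwise by Kruskal-Wallis with Dunn's
rank test, reporting Bonferroni and Holm adjustments side by side.
Significance groups are summarized as letters: strains sharing no letter
differ at the chosen alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    test_used: str                     # "anova_tukey" | "kruskal_dunn"
    normality_p: float
    omnibus_p: float
    alpha: float
    group_letters: dict[str, str]      # strain -> letters (e.g. "ab")
    pairwise: pd.DataFrame             # strain_a, strain_b, p_adj (+ extras)
    group_means: dict[str, float] = field(default_factory=dict)


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z test on mean ranks after Kruskal-Wallis, with the
    standard tie correction; returns raw two-sided p plus Bonferroni and
    Holm adjusted p-values."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    i = 0
    for g in names:
        k = len(groups[g])
        mean_ranks[g] = ranks[i : i + k].mean()
        i += k
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"strain_a": a, "strain_b": b, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = multipletests(df["p_raw"], method="bonferroni")[1]
    df["p_holm"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def compact_letter_display(
    names: list[str],
    means: dict[str, float],
    significant: set[frozenset[str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Guarantees: every significantly different pair shares no letter, every
    non-significant pair shares at least one. Deterministic: strains are
    processed sorted by mean (descending, name tie-break) and letters
    assigned in order.
    """
    order = sorted(names, key=lambda s: (-means[s], s))
    groups: list[set[str]] = [set(order)]
    for a, b in itertools.combinations(order, 2):
        if frozenset((a, b)) not in significant:
            continue
        for g in [g for g in groups if a in g and b in g]:
            groups.remove(g)
            groups.extend([g - {a}, g - {b}])
        # absorb: drop groups that are subsets of others
        groups = [
            g for g in groups
            if g and not any(g < h for h in groups if h is not g)
        ]
        # deduplicate
        uniq: list[set[str]] = []
        for g in groups:
            if g not in uniq:
                uniq.append(g)
        groups = uniq
    # order letter groups by the best (largest) member mean for stable output
    groups.sort(key=lambda g: (min(order.index(s) for s in g), -len(g)))
    letters = {s: "" for s in order}
    for i, g in enumerate(groups):
        ch = chr(ord("a") + i) if i < 26 else f"({i})"
        for s in order:
            if s in g:
                letters[s] += ch
    return letters


def compare_strains(
    replicates: dict[str, list[float]] | pd.DataFrame,
    alpha: float = 0.05,
) -> StatResult:
    """Omnibus + post-hoc comparison of replicate rates across strains.

    Shapiro-Wilk on the residuals (value minus group mean) gates the
    branch: p < 0.05 selects Kruskal-Wallis with Dunn (Bonferroni p used
    for letters, Holm reported alongside); otherwise one-way ANOVA with
    Tukey HSD.
    """
    if isinstance(replicates, pd.DataFrame):
        groups = {
            str(s): sub["rate"].to_numpy(dtype=float)
            for s, sub in replicates.groupby("strain", sort=False)
        }
    else:
        groups = {s: np.asarray(v, dtype=float) for s, v in replicates.items()}
    if len(groups) < 2:
        raise ValueError("need at least two strains")
    for s, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"strain {s!r} has fewer than 2 replicates")

    names = list(groups)
    means = {s: float(np.mean(v)) for s, v in groups.items()}
    residuals = np.concatenate([v - means[s] for s, v in groups.items()])
    if np.allclose(residuals, residuals[0]):
        normality_p = 1.0   # zero-variance residuals: treat as normal branch
    else:
        normality_p = float(stats.shapiro(residuals).pvalue)

    values = [groups[s] for s in names]
    all_equal = all(
        np.array_equal(values[0], v) and np.ptp(v) == 0 for v in values
    )
    if all_equal:
        # identical constant groups: no test can distinguish anything
        letters = compact_letter_display(names, means, set())
        return StatResult(
            test_used="anova_tukey", normality_p=normality_p, omnibus_p=1.0,
            alpha=alpha, group_letters=letters,
            pairwise=pd.DataFrame(
                {"strain_a": [], "strain_b": [], "p_adj": []}
            ),
            group_means=means,
        )

    if normality_p < 0.05:
        omnibus_p = float(stats.kruskal(*values).pvalue)
        pw = dunn_test(groups)
        pw["p_adj"] = pw["p_bonferroni"]
        test_used = "kruskal_dunn"
    else:
        omnibus_p = float(stats.f_oneway(*values).pvalue)
        flat = np.concatenate(values)
        labels = np.concatenate([[s] * len(groups[s]) for s in names])
        tuk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        pw = pd.DataFrame(
            tuk.summary().data[1:], columns=tuk.summary().data[0]
        ).rename(columns={"group1": "strain_a", "group2": "strain_b",
                          "p-adj": "p_adj"})
        pw["p_adj"] = pw["p_adj"].astype(float)
        test_used = "anova_tukey"

    significant = {
        frozenset((r.strain_a, r.strain_b))
        for r in pw.itertuples()
        if r.p_adj < alpha
    }
    letters = compact_letter_display(names, means, significant)
    return StatResult(
        test_used=test_used, normality_p=normality_p, omnibus_p=omnibus_p,
        alpha=alpha, group_letters=letters, pairwise=pw, group_means=means,
    )
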