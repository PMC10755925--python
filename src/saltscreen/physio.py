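"""Physiology index formulas and group-comparison statistics.

Covers the two index formulas that are pure arithmetic on raw
measurements —

* relative water content  ``RWC = 100 * (FW - DW) / (TW - DW)``
* relative electrolyte leakage  ``REL = 100 * C1 / C2``

— and the statistics behind letter-annotated bar charts: one-way ANOVA,
Tukey HSD pairwise comparisons, a compact letter display (groups
sharing a letter are not significantly different), and two-sample
t-tests (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def rwc(fresh: float, turgid: float, dry: float) -> float:
    """Relative water content (%) from fresh, turgid and dry mass."""
    if turgid <= dry:
        raise ValueError("turgid mass must exceed dry mass")
    if fresh < dry:
        raise ValueError("fresh mass cannot be below dry mass")
    return 100.0 * (fresh - dry) / (turgid - dry)


def rel(conductivity_initial: float, conductivity_boiled: float) -> float:
    """Relative electrolyte leakage (%) from pre/post-boiling conductivity."""
    if conductivity_boiled <= 0:
        raise ValueError("post-boiling conductivity must be positive")
    if conductivity_initial < 0 or conductivity_initial > conductivity_boiled:
        raise ValueError("initial conductivity must lie in [0, boiled conductivity]")
    return 100.0 * conductivity_initial / conductivity_boiled


def _check_groups(groups: list[np.ndarray], min_n: int = 2) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(g) < min_n:
            raise ValueError(f"group {i} has n={len(g)} < {min_n}")
    return groups


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value.

    By convention F = 0 (p = 1) when there is no variation at all
    (every value identical), where the F ratio is 0/0.
    """
    groups = _check_groups(groups)
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def two_sample_t(x: np.ndarray, y: np.ndarray, welch: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (Welch degrees of freedom by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


@dataclass
class GroupComparison:
    """ANOVA + Tukey HSD + compact letter display for labelled groups."""

    labels: list[str]
    means: pd.Series
    f_stat: float
    p_anova: float
    pairwise_p: pd.DataFrame  # symmetric, NaN diagonal-free (1.0 on diagonal)
    letters: dict[str, str]
    alpha: float


def tukey_pairwise_p(groups: list[np.ndarray]) -> np.ndarray:
    """All-pairs Tukey HSD p-values from the studentized range distribution."""
    res = stats.tukey_hsd(*groups)
    return np.asarray(res.pvalue)


def compact_letter_display(
    labels: list[str], means: np.ndarray, distinct: np.ndarray
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``distinct[i, j]`` flags a significant difference between groups i
    and j.  Letters are assigned over groups sorted by descending mean,
    starting at 'a' for the top group; groups sharing any letter are
    not significantly different.
    """
    order = sorted(range(len(labels)), key=lambda i: (-means[i], labels[i]))
    # letter groups: list of sets of group indices that may share a letter
    letter_sets: list[set[int]] = [set(order)]
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            gi, gj = order[i], order[j]
            if not distinct[gi, gj]:
                continue
            new_sets = []
            for s in letter_sets:
                if gi in s and gj in s:
                    # split: duplicate the set without each offender
                    new_sets.append(s - {gj})
                    new_sets.append(s - {gi})
                else:
                    new_sets.append(s)
            # absorb: drop sets contained in another
            letter_sets = [
                s for s in new_sets
                if not any(s < t for t in new_sets)
            ]
            # dedupe while preserving order
            seen = []
            for s in letter_sets:
                if s not in seen:
                    seen.append(s)
            letter_sets = seen
    # order letter sets by the best (largest-mean) group they contain
    rank_of = {g: r for r, g in enumerate(order)}
    letter_sets.sort(key=lambda s: min(rank_of[g] for g in s))
    letters: dict[str, str] = {lab: "" for lab in labels}
    for idx, s in enumerate(letter_sets):
        ch = chr(ord("a") + idx)
        for g in sorted(s, key=lambda g: rank_of[g]):
            letters[labels[g]] += ch
    return letters


def tukey_cld(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    alpha: float = 0.05,
    labels: list[str] | None = None,
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise tests and letter display."""
    if isinstance(groups, dict):
        labels = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = labels or [f"g{i + 1}" for i in range(len(data))]
    data = _check_groups(data)
    f, p_anova = anova_oneway(data)
    if np.ptp(np.concatenate(data)) == 0:
        k = len(data)
        pairwise = np.ones((k, k))
    else:
        pairwise = tukey_pairwise_p(data)
    means = np.array([g.mean() for g in data])
    distinct = pairwise < alpha
    np.fill_diagonal(distinct, False)
    letters = compact_letter_display(labels, means, distinct)
    return GroupComparison(
        labels=labels,
        means=pd.Series(means, index=labels),
        f_stat=f,
        p_anova=p_anova,
        pairwise_p=pd.DataFrame(pairwise, index=labels, columns=labels),
        letters=letters,
        alpha=alpha,
    )


def compare_physio(series: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Letter displays per (variable, day) across genotype x treatment groups.

    ``series`` is the tidy physiology table (genotype, treatment, day,
    variable, replicate, value).  Returns one row per group per cell
    with mean, sd, n and its letter.
    """
    rows = []
    for (variable, day), cell in series.groupby(["variable", "day"], sort=True):
        groups = {
            f"{gen}_{trt}": grp["value"].to_numpy()
            for (gen, trt), grp in cell.groupby(["genotype", "treatment"], sort=True)
        }
        comp = tukey_cld(groups, alpha=alpha)
        for label in comp.labels:
            sample = groups[label]
            rows.append(
                {
                    "variable": variable,
                    "day": day,
                    "group": label,
                    "n": len(sample),
                    "mean": sample.mean(),
                    "sd": sample.std(ddof=1),
                    "letters": comp.letters[label],
                    "f_stat": comp.f_stat,
                    "p_anova": comp.p_anova,
                }
            )
    return pd.DataFrame(rows)
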