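"""Correlation-based trait pruning.

Most trait tolerance coefficients in a salt screen are driven by the
same underlying tolerance and are therefore positively inter-correlated
across accessions.  A trait whose STC is essentially uncorrelated with
every other trait (the classic offenders are ratio-type traits such as
root-bud ratio, or average root diameter) carries no evaluation signal
and is pruned before the principal-component step.

The codified rule: a trait is dropped when it has fewer than
``min_significant_positive`` (default 2) significant positive Pearson
correlations (p < ``alpha_screen``, default 0.01) with the other traits.
Negative correlations never count toward retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .tolerance import ToleranceMatrix


@dataclass
class CorrelationReport:
    """Pairwise Pearson r and p among trait STC columns, plus the screen verdict."""

    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    significant_positive_count: pd.Series = field(default=None)
    retained: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)  # trait -> reason


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with the two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(matrix: ToleranceMatrix) -> CorrelationReport:
    """All pairwise trait correlations of the STC matrix.

    Constant trait columns get NaN r and p against every partner (and
    count zero significant correlations); the diagonal is exactly 1.
    """
    stc = matrix.stc
    n = len(stc)
    if n < 3:
        raise ValueError("need at least 3 accessions for correlation analysis")
    traits = list(stc.columns)
    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    values = stc.to_numpy()
    constant = np.ptp(values, axis=0) == 0
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                continue
            r[i, j], p[i, j] = pearson_with_p(values[:, i], values[:, j])
            r[j, i], p[j, i] = r[i, j], p[i, j]
    r_df = pd.DataFrame(r, index=traits, columns=traits)
    p_df = pd.DataFrame(p, index=traits, columns=traits)
    return CorrelationReport(traits=traits, r=r_df, p=p_df, n=n)


def screen_traits(report: CorrelationReport, cfg: PipelineConfig | None = None) -> CorrelationReport:
    """Apply the pruning rule; fills retained/dropped on the report.

    With ``cfg.bonferroni`` the per-pair alpha is divided by the number
    of unique off-diagonal pairs.
    """
    cfg = cfg or PipelineConfig()
    k = len(report.traits)
    alpha = cfg.alpha_screen
    if cfg.bonferroni and k > 1:
        alpha = alpha / (k * (k - 1) / 2)

    off_diag = ~np.eye(k, dtype=bool)
    sig_pos = (
        (report.p.to_numpy() < alpha) & (report.r.to_numpy() > 0) & off_diag
    )
    counts = pd.Series(sig_pos.sum(axis=1), index=report.traits)
    report.significant_positive_count = counts

    retained, dropped = [], {}
    for trait in report.traits:
        c = int(counts[trait])
        if c < cfg.min_significant_positive:
            dropped[trait] = (
                f"{c} significant positive correlation(s) at p<{cfg.alpha_screen:g} "
                f"(minimum {cfg.min_significant_positive})"
            )
        else:
            retained.append(trait)
    if len(retained) < 2:
        raise ValueError(
            f"screening would retain {len(retained)} trait(s); at least 2 required"
        )
    report.retained = retained
    report.dropped = dropped
    return report


def screening_table(report: CorrelationReport) -> pd.DataFrame:
    """Per-trait decision table (trait, n significant positive, decision, reason)."""
    rows = []
    for trait in report.traits:
        kept = trait in report.retained
        rows.append(
            {
                "trait": trait,
                "significant_positive": int(report.significant_positive_count[trait]),
                "decision": "retained" if kept else "dropped",
                "reason": "" if kept else report.dropped[trait],
            }
        )
    return pd.DataFrame(rows)
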