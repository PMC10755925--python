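"""Relative expression by the 2^-ddCt (Livak) method and the
qPCR vs. RNA-seq concordance check.

Per condition, the target gene's mean Ct is normalized against the
reference gene (dCt = mean Ct_target - mean Ct_reference); the
treatment-vs-control difference ddCt = dCt_treatment - dCt_control
converts to a fold change 2^-ddCt.  Replicates are averaged on the Ct
(cycle) scale, the Livak convention, and amplification efficiency is
taken as exactly 2 per cycle.

Concordance between qPCR and RNA-seq fold changes is the R-squared of
an ordinary least-squares fit between the two log2 fold-change vectors
(fold changes are multiplicative, so the log scale is the natural one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "condition", "gene", "is_reference", "ct"]
CONDITIONS = ("control", "treatment")


@dataclass
class FoldChangeRecord:
    gene: str
    delta_ct_control: float
    delta_ct_treatment: float
    delta_delta_ct: float
    fold_change: float


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {missing}")
    refs = set(table.loc[table["is_reference"].astype(bool), "gene"])
    if len(refs) != 1:
        raise ValueError(f"exactly one reference gene required, found {sorted(refs)}")
    ct = table["ct"].to_numpy(dtype=float)
    if not ((ct > 0) & (ct < 45)).all():
        raise ValueError("Ct values must lie in (0, 45) cycles")
    bad_cond = set(table["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition(s): {sorted(bad_cond)}")
    return table


def _mean_ct(table: pd.DataFrame, gene: str, condition: str) -> float:
    sel = table[(table["gene"] == gene) & (table["condition"] == condition)]
    if sel.empty:
        raise ValueError(f"no Ct values for gene {gene!r} under {condition!r}")
    return float(sel["ct"].mean())


def delta_delta_ct(table: pd.DataFrame, gene: str) -> FoldChangeRecord:
    """Fold change of ``gene`` (treatment vs. control) by 2^-ddCt."""
    table = validate_ct_table(table)
    reference = table.loc[table["is_reference"].astype(bool), "gene"].iloc[0]
    if gene == reference:
        raise ValueError("the reference gene cannot be quantified against itself")
    d_ct = {}
    for condition in CONDITIONS:
        d_ct[condition] = _mean_ct(table, gene, condition) - _mean_ct(
            table, reference, condition
        )
    ddct = d_ct["treatment"] - d_ct["control"]
    return FoldChangeRecord(
        gene=gene,
        delta_ct_control=d_ct["control"],
        delta_ct_treatment=d_ct["treatment"],
        delta_delta_ct=ddct,
        fold_change=float(2.0 ** (-ddct)),
    )


def fold_change_table(table: pd.DataFrame) -> pd.DataFrame:
    """2^-ddCt fold changes for every non-reference gene in the table."""
    table = validate_ct_table(table)
    targets = sorted(set(table.loc[~table["is_reference"].astype(bool), "gene"]))
    records = [delta_delta_ct(table, g) for g in targets]
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "delta_ct_control": [r.delta_ct_control for r in records],
            "delta_ct_treatment": [r.delta_ct_treatment for r in records],
            "delta_delta_ct": [r.delta_delta_ct for r in records],
            "fold_change": [r.fold_change for r in records],
        }
    )


def concordance(qpcr_folds: pd.Series | dict, rnaseq_folds: pd.Series | dict) -> float:
    """R-squared between log2 qPCR and log2 RNA-seq fold changes (shared genes)."""
    q = pd.Series(qpcr_folds, dtype=float)
    r = pd.Series(rnaseq_folds, dtype=float)
    shared = sorted(set(q.index) & set(r.index))
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared genes, have {len(shared)}")
    q, r = q[shared], r[shared]
    if (q <= 0).any() or (r <= 0).any():
        raise ValueError("fold changes must be positive")
    fit = stats.linregress(np.log2(r.to_numpy()), np.log2(q.to_numpy()))
    return float(fit.rvalue ** 2)
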