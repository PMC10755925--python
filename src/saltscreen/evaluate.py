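"""Comprehensive evaluation: PCA, fuzzy membership, weights, D values.

The screened STC matrix is standardized per trait and decomposed into
principal components of the trait correlation matrix.  Components with
eigenvalue above the retention threshold (Kaiser rule, > 1 by default)
become composite salt-tolerance indicators.  Accession scores on each
retained component are rescaled to [0, 1] by the fuzzy membership
(subordinate) function

    u_k(i) = (F_k(i) - min_i F_k) / (max_i F_k - min_i F_k),

weighted by the components' relative contribution rates

    w_k = P_k / sum_retained P_k,      P_k = 100 * lambda_k / sum lambda,

and combined into the final tolerance score

    D(i) = sum_k w_k * u_k(i),

ranked descending (rank 1 = most salt-tolerant).

Eigenvector sign is arbitrary; each retained loading column is oriented
so its loading sum is non-negative (tie broken by making the largest-
magnitude loading positive).  Because every trait is higher-is-better,
this makes a higher composite score mean more tolerant and renders the
whole evaluation deterministic under row/column permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .tolerance import ToleranceMatrix


@dataclass
class PCAModel:
    """Eigenstructure of the standardized STC matrix."""

    trait_means: pd.Series
    trait_sds: pd.Series
    eigenvalues: np.ndarray  # descending
    loadings: pd.DataFrame  # traits x components (PC1, PC2, ...)
    contribution_pct: np.ndarray
    cumulative_pct: np.ndarray
    retained: list[int]  # 0-based component indices
    scores: pd.DataFrame  # accessions x retained components

    def eigen_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [f"PC{k + 1}" for k in range(len(self.eigenvalues))],
                "eigenvalue": self.eigenvalues,
                "contribution_pct": self.contribution_pct,
                "cumulative_pct": self.cumulative_pct,
                "retained": [k in self.retained for k in range(len(self.eigenvalues))],
            }
        )


@dataclass
class EvaluationResult:
    """Memberships, weights, D values and ranks for one cohort."""

    model: PCAModel
    membership: pd.DataFrame  # accessions x retained components, in [0, 1]
    weights: pd.Series  # per retained component, sums to 1
    d_value: pd.Series  # per accession, in [0, 1]
    rank: pd.Series  # 1 = most tolerant; ties share the minimum rank

    def ranking_table(self) -> pd.DataFrame:
        df = pd.DataFrame({"accession": self.d_value.index, "d_value": self.d_value.values})
        df["rank"] = self.rank.values
        return df.sort_values(["rank", "accession"], kind="mergesort").reset_index(drop=True)


def standardize(matrix: ToleranceMatrix) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-standardize the STC matrix (mean 0, sample sd 1, n-1 denominator)."""
    stc = matrix.stc
    if len(stc) < 3:
        raise ValueError("need at least 3 accessions")
    means = stc.mean(axis=0)
    sds = stc.std(axis=0, ddof=1)
    constant = sds[sds == 0]
    if len(constant):
        raise ValueError(f"constant trait column(s): {list(constant.index)}")
    z = (stc - means) / sds
    return z, means, sds


def _orient_sign(loadings: np.ndarray) -> np.ndarray:
    """Flip each loading column so its sum is >= 0 (tie: largest |loading| > 0)."""
    oriented = loadings.copy()
    for k in range(oriented.shape[1]):
        col = oriented[:, k]
        s = col.sum()
        if abs(s) < 1e-12:
            pivot = np.argmax(np.abs(col))
            s = col[pivot]
        if s < 0:
            oriented[:, k] = -col
    return oriented


def pca_fit(z: pd.DataFrame, cfg: PipelineConfig | None = None,
            means: pd.Series | None = None, sds: pd.Series | None = None) -> PCAModel:
    """Eigendecomposition of the trait correlation matrix of ``z``.

    ``z`` must already be column-standardized, so the correlation matrix
    is ``z.T @ z / (n - 1)``.  Components are sorted by descending
    eigenvalue and sign-oriented; retained components are those with
    eigenvalue above ``cfg.eigenvalue_threshold`` (falling back to the
    first component, with a warning, if none qualifies).  Scores are
    ``z @ loadings`` for the retained columns.
    """
    cfg = cfg or PipelineConfig()
    n, k = z.shape
    if n < 3:
        raise ValueError("need at least 3 accessions")
    corr = z.to_numpy().T @ z.to_numpy() / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = _orient_sign(eigvecs[:, order])

    total = eigvals.sum()
    contribution = 100.0 * eigvals / total
    cumulative = np.cumsum(contribution)
    retained = [i for i, lam in enumerate(eigvals) if lam > cfg.eigenvalue_threshold]
    if not retained:
        warnings.warn(
            "no eigenvalue exceeds the retention threshold; retaining PC1 only",
            stacklevel=2,
        )
        retained = [0]

    comp_names = [f"PC{i + 1}" for i in range(k)]
    loadings = pd.DataFrame(eigvecs, index=z.columns, columns=comp_names)
    scores = pd.DataFrame(
        z.to_numpy() @ eigvecs[:, retained],
        index=z.index,
        columns=[comp_names[i] for i in retained],
    )
    if means is None:
        means = pd.Series(0.0, index=z.columns)
    if sds is None:
        sds = pd.Series(1.0, index=z.columns)
    return PCAModel(
        trait_means=means,
        trait_sds=sds,
        eigenvalues=eigvals,
        loadings=loadings,
        contribution_pct=contribution,
        cumulative_pct=cumulative,
        retained=retained,
        scores=scores,
    )


def membership(scores: pd.Series | np.ndarray) -> np.ndarray:
    """Fuzzy membership u = (F - min) / (max - min); all 0.5 when degenerate."""
    f = np.asarray(scores, dtype=float)
    if len(f) < 2:
        raise ValueError("membership needs at least 2 accessions")
    lo, hi = f.min(), f.max()
    if hi == lo:
        return np.full_like(f, 0.5)
    return (f - lo) / (hi - lo)


def weights(model: PCAModel) -> pd.Series:
    """Contribution-rate weights renormalized over the retained components."""
    p = model.contribution_pct[model.retained]
    w = p / p.sum()
    return pd.Series(w, index=model.scores.columns)


def d_value_and_rank(u: pd.DataFrame, w: pd.Series, model: PCAModel) -> EvaluationResult:
    """Weighted-membership D value per accession, ranked descending.

    Ties share the minimum rank; the ranking table breaks ties by
    accession id for a deterministic display order.
    """
    if list(u.columns) != list(w.index):
        raise ValueError("membership columns and weight index do not agree")
    d = pd.Series(u.to_numpy() @ w.to_numpy(), index=u.index, name="d_value")
    d = d.sort_index()
    rank = d.rank(method="min", ascending=False).astype(int)
    return EvaluationResult(model=model, membership=u, weights=w, d_value=d, rank=rank)


def evaluate(matrix: ToleranceMatrix, cfg: PipelineConfig | None = None) -> EvaluationResult:
    """Full evaluation of a (screened) STC matrix: standardize -> PCA ->
    membership per retained component -> contribution weights -> D -> rank."""
    cfg = cfg or PipelineConfig()
    z, means, sds = standardize(matrix)
    model = pca_fit(z, cfg, means=means, sds=sds)
    u = pd.DataFrame(
        {name: membership(model.scores[name]) for name in model.scores.columns},
        index=model.scores.index,
    )
    w = weights(model)
    return d_value_and_rank(u, w, model)
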