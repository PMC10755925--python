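"""Independent numerical oracles used only by the tests.

The eigen oracle deliberately avoids ``numpy.linalg.eigh`` (the
production path): characteristic-polynomial coefficients come from the
Faddeev-LeVerrier trace recursion, eigenvalues from polynomial root
finding, and eigenvectors from shifted inverse iteration.
"""

import numpy as np


def charpoly_coefficients(c: np.ndarray) -> np.ndarray:
    """Coefficients of det(lambda I - C) via Faddeev-LeVerrier."""
    n = c.shape[0]
    coeffs = np.zeros(n + 1)
    coeffs[0] = 1.0
    m = np.eye(n)
    for k in range(1, n + 1):
        cm = c @ m
        coeffs[k] = -np.trace(cm) / k
        m = cm + coeffs[k] * np.eye(n)
    return coeffs


def inverse_iteration(c: np.ndarray, lam: float, n_iter: int = 200, seed: int = 0) -> np.ndarray:
    """Eigenvector for eigenvalue ``lam`` by shifted inverse iteration."""
    n = c.shape[0]
    rng = np.random.default_rng(seed)
    v = rng.normal(size=n)
    v /= np.linalg.norm(v)
    shifted = c - (lam + 1e-10) * np.eye(n)
    for _ in range(n_iter):
        try:
            w = np.linalg.solve(shifted, v)
        except np.linalg.LinAlgError:
            shifted = c - (lam + 1e-8) * np.eye(n)
            w = np.linalg.solve(shifted, v)
        w_norm = np.linalg.norm(w)
        if not np.isfinite(w_norm) or w_norm == 0:
            break
        w = w / w_norm
        if np.linalg.norm(w - v) < 1e-15 or np.linalg.norm(w + v) < 1e-15:
            v = w
            break
        v = w
    return v


def brute_force_eigh(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and eigenvectors of a symmetric matrix,
    via characteristic-polynomial roots + inverse iteration."""
    coeffs = charpoly_coefficients(c)
    roots = np.roots(coeffs)
    eigvals = np.sort(roots.real)[::-1]
    vecs = np.column_stack([inverse_iteration(c, lam) for lam in eigvals])
    return eigvals, vecs


def permutation_t_pvalue(x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p-value for the difference of means."""
    pooled = np.concatenate([x, y])
    n = len(x)
    obs = abs(x.mean() - y.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += abs(perm[:n].mean() - perm[n:].mean()) >= obs - 1e-12
    return count / n_perm


def permutation_pairwise_decisions(
    groups: list[np.ndarray], alpha: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Pairwise significant/not decisions from per-pair permutation tests
    (no multiplicity adjustment; a deliberately simple independent check)."""
    k = len(groups)
    distinct = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            p = permutation_t_pvalue(groups[i], groups[j], n_perm, rng)
            distinct[i, j] = distinct[j, i] = p < alpha
    return distinct
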