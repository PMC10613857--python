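"""Data-driven symptom structure: PCA of the MADRS items with oblique rotation.

Extraction is principal components of the item correlation matrix (not a
common-factor fit): eigenvalues sum to the number of items, and the
unrotated loading of component k is ``eigenvector_k * sqrt(eigenvalue_k)``.
A fixed number of components (five by default, one per hypothesized
symptom domain) is retained and obliquely rotated with direct oblimin
(delta = 0, i.e. quartimin), allowing the resulting factors to correlate,
as depressive symptom clusters do.  Factor scores use the regression
(Thurstone) method: ``scores = Z R^+ (P Phi)`` with standardized items Z,
pattern P and factor correlations Phi.

The oblimin rotation is solved by the standard oblique gradient-projection
algorithm (Jennrich 2002); correctness is pinned down by its invariants --
the rotated solution reproduces the unrotated low-rank structure
(``P Phi P' = A A'``), the criterion decreases monotonically, and planted
block loadings are recovered up to column order and sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class FactorSolution:
    """Rotated PCA solution for an item battery.

    Attributes
    ----------
    loadings:
        items x factors pattern matrix after oblique rotation.
    factor_correlations:
        factors x factors correlation matrix of the oblique factors.
    eigenvalues:
        All eigenvalues of the item correlation matrix, descending.
    explained_variance_pct:
        Per-component percentage of total variance (eigenvalue / n_items).
    score_coefficients:
        items x factors regression weights applied to standardized items.
    scores:
        n_patients x factors factor scores (zero mean per factor).
    item_names:
        Column labels of the input table, in order.
    """

    loadings: np.ndarray
    factor_correlations: np.ndarray
    eigenvalues: np.ndarray
    explained_variance_pct: np.ndarray
    score_coefficients: np.ndarray
    scores: np.ndarray
    item_names: tuple[str, ...]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def cumulative_explained_variance_pct(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_pct)


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Quartimin criterion (direct oblimin, delta 0) and its gradient in L."""
    L2 = L**2
    N = np.ones((L.shape[1], L.shape[1])) - np.eye(L.shape[1])
    X = L2 @ N
    f = float(np.sum(L2 * X)) / 4.0
    return f, L * X


def oblimin_rotate(
    A: np.ndarray, max_iter: int = 1000, tol: float = 1e-8, n_starts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Direct-oblimin (quartimin) rotation by oblique gradient projection.

    The criterion is non-convex, so the gradient-projection iteration is
    restarted from the identity plus ``n_starts`` seeded random oblique
    transforms and the solution with the lowest criterion value is kept
    (deterministic across calls).

    Parameters
    ----------
    A:
        Unrotated loading matrix (items x factors).
    Returns
    -------
    (pattern, phi):
        Rotated pattern matrix and factor correlation matrix.
    """
    A = np.asarray(A, dtype=float)
    k = A.shape[1]
    rng = np.random.default_rng(k)
    starts = [np.eye(k)]
    for _ in range(n_starts):
        T0 = rng.normal(size=(k, k))
        T0 /= np.sqrt(np.sum(T0**2, axis=0))
        starts.append(T0)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for T0 in starts:
        L, phi, f = _gpa_oblique(A, T0, max_iter, tol)
        if best is None or f < best[0]:
            best = (f, L, phi)
    return best[1], best[2]


def _gpa_oblique(
    A: np.ndarray, T: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float]:
    k = A.shape[1]
    T = T.copy()
    L = np.linalg.solve(T, A.T).T
    f, Gq = _quartimin(L)
    G = -np.linalg.solve(T.T, Gq.T @ L)
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)  # project onto the oblique manifold
        s = float(np.linalg.norm(Gp))
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            X /= np.sqrt(np.sum(X**2, axis=0))  # unit-length columns
            Lt = np.linalg.solve(X, A.T).T  # L = A (X')^{-1}
            ft, Gq = _quartimin(Lt)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, L, f = X, Lt, ft
        G = -np.linalg.solve(T.T, Gq.T @ L)
    phi = T.T @ T
    return L, phi, f


def _apply_sign_convention(
    pattern: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-magnitude loading of each factor positive."""
    signs = np.ones(pattern.shape[1])
    for j in range(pattern.shape[1]):
        i = int(np.argmax(np.abs(pattern[:, j])))
        if pattern[i, j] < 0:
            signs[j] = -1.0
    S = np.diag(signs)
    return pattern @ S, S @ phi @ S


def fit_factors(item_table, n_factors: int = 5) -> FactorSolution:
    """PCA of the item correlation matrix with oblimin-rotated components.

    Parameters
    ----------
    item_table:
        DataFrame or array of shape (n_patients, n_items); at least two
        patients, no constant column.
    n_factors:
        Number of components retained for rotation (default five, the
        hypothesized number of symptom domains).
    """
    if isinstance(item_table, pd.DataFrame):
        names = tuple(str(c) for c in item_table.columns)
        X = item_table.to_numpy(dtype=float)
    else:
        X = np.asarray(item_table, dtype=float)
        names = tuple(f"item_{j + 1}" for j in range(X.shape[1]))
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("item table must be 2D with at least two patients")
    n, p = X.shape
    if not 1 <= n_factors <= p:
        raise ValueError(f"n_factors must be in 1..{p}, got {n_factors}")
    sd = X.std(axis=0, ddof=1)
    constant = [names[j] for j in range(p) if sd[j] == 0]
    if constant:
        raise ValueError(f"constant item column(s): {constant}")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)

    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)  # guard tiny negatives from roundoff
    A = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])

    if n_factors == 1:
        pattern, phi = A.copy(), np.ones((1, 1))
    else:
        pattern, phi = oblimin_rotate(A)
    pattern, phi = _apply_sign_convention(pattern, phi)

    structure = pattern @ phi
    W = np.linalg.pinv(R) @ structure  # regression-method score weights
    scores = Z @ W
    return FactorSolution(
        loadings=pattern,
        factor_correlations=phi,
        eigenvalues=eigval,
        explained_variance_pct=eigval / p * 100.0,
        score_coefficients=W,
        scores=scores,
        item_names=names,
    )


def explained_variance_at(solution: FactorSolution, k: int) -> float:
    """Cumulative explained variance (%) of the first k unrotated components."""
    p = len(solution.eigenvalues)
    if not 0 <= k <= p:
        raise ValueError(f"k must be in 0..{p}")
    return float(solution.eigenvalues[:k].sum() / p * 100.0)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading columns."""
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def match_factors(
    recovered: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match recovered loading columns to target columns by |congruence|.

    Returns ``(permutation, congruences)`` where ``permutation[j]`` is the
    recovered column assigned to target column ``j`` and ``congruences[j]``
    the absolute Tucker congruence of that pair.  Used both to score
    planted-structure recovery and to pair data-driven factors with
    conceptual domains for map comparison.
    """
    recovered, target = np.asarray(recovered, float), np.asarray(target, float)
    k = target.shape[1]
    C = np.zeros((k, recovered.shape[1]))
    for j in range(k):
        for l in range(recovered.shape[1]):
            C[j, l] = abs(tucker_congruence(target[:, j], recovered[:, l]))
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(k, dtype=int)
    cong = np.empty(k)
    for r, c in zip(rows, cols):
        perm[r], cong[r] = c, C[r, c]
    return perm, cong
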