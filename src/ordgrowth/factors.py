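"""Exploratory factor analysis for clinical laboratory panels.

Data-reduction stage: principal-component extraction from the correlation
matrix, Kaiser retention (eigenvalue > 1), varimax rotation with Kaiser
row normalization, loading-strength classification (weak < 0.4,
moderate 0.4-0.6, strong > 0.6) and regression-method factor scores.
Rotated factor scores of laboratory panels (white cell, red cell, blood
chemistry, protein/lipid blocks) then enter the longitudinal model as
time-varying covariates.

Varimax is implemented by the classic cycle of pairwise planar rotations,
which maximizes the varimax criterion (the sum over factors of the variance
of squared loadings).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "FactorSolution",
    "extract_components",
    "varimax_rotate",
    "varimax_criterion",
    "classify_loadings",
    "score_factors",
]

_KAISER_TOL = 1e-10


@dataclass
class FactorSolution:
    """Result of extraction (and optionally rotation) of a clinical panel.

    ``loadings`` is variables x retained-factors; ``rotation`` the orthogonal
    matrix R with ``loadings = unrotated_loadings @ R``; row sums of squared
    loadings (communalities) are invariant under rotation.
    """

    eigenvalues: np.ndarray  # all eigenvalues, descending
    loadings: np.ndarray  # (n_vars, n_retained)
    rotation: np.ndarray  # (n_retained, n_retained), orthogonal
    variance_explained: float  # cumulative fraction, retained factors
    scoring_weights: np.ndarray  # (n_vars, n_retained)
    variable_names: list
    factor_names: list
    corr: np.ndarray  # correlation matrix used for extraction/scoring
    converged: bool = True

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings**2).sum(axis=1)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.variable_names, columns=self.factor_names)


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i+1}" for i in range(X.shape[1])]


def extract_components(X) -> FactorSolution:
    """Principal-component extraction from the correlation matrix.

    Eigendecomposition of the sample correlation matrix; loadings are
    eigenvectors scaled by the square root of their eigenvalues; factors
    with eigenvalue > 1 are retained (Kaiser criterion, strict: eigenvalues
    within 1e-10 of 1 are dropped).  ``variance_explained`` is the retained
    eigenvalue mass over the number of variables.
    """
    arr, names = _as_matrix(X)
    n, p = arr.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    sd = arr.std(axis=0, ddof=1)
    bad = [names[i] for i in np.nonzero(sd == 0)[0]]
    if bad:
        raise ValueError(f"zero-variance columns: {bad}")
    R = np.corrcoef(arr, rowvar=False)
    if not np.all(np.isfinite(R)):
        nan_cols = [names[i] for i in np.nonzero(~np.isfinite(R).all(axis=0))[0]]
        raise ValueError(f"correlation matrix has non-finite entries involving: {nan_cols}")
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    retained = int(np.sum(evals > 1.0 + _KAISER_TOL))
    load = evecs[:, :retained] * np.sqrt(np.clip(evals[:retained], 0, None))
    # deterministic sign: largest-magnitude loading of each factor positive
    load = _fix_signs(load)
    weights = np.linalg.solve(R, load) if retained else np.zeros((p, 0))
    return FactorSolution(
        eigenvalues=evals,
        loadings=load,
        rotation=np.eye(retained),
        variance_explained=float(evals[:retained].sum() / p),
        scoring_weights=weights,
        variable_names=names,
        factor_names=[f"factor{i+1}" for i in range(retained)],
        corr=R,
    )


def _fix_signs(load: np.ndarray) -> np.ndarray:
    if load.shape[1] == 0:
        return load
    idx = np.argmax(np.abs(load), axis=0)
    signs = np.sign(load[idx, np.arange(load.shape[1])])
    signs[signs == 0] = 1.0
    return load * signs


def varimax_criterion(load: np.ndarray) -> float:
    """Sum over factors of the variance of squared loadings."""
    sq = load**2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(
    solution: FactorSolution,
    tol: float = 1e-10,
    max_iter: int = 100,
    kaiser_normalize: bool = True,
) -> FactorSolution:
    """Varimax rotation by iterated pairwise planar rotations.

    Sweeps over all factor pairs, rotating each pair by the closed-form
    optimal angle, until the criterion gain over a full sweep drops below
    ``tol``.  Kaiser normalization (rows scaled to unit communality before
    rotation) is applied by default; because the rotation acts on columns,
    the de-normalized result still satisfies ``rotated = unrotated @ R``
    exactly, so communalities are preserved to machine precision.

    Factors are re-ordered by explained variance and signed so each factor's
    largest-magnitude loading is positive.  A single retained factor is
    returned unchanged.
    """
    L0 = solution.loadings
    p, m = L0.shape
    if m < 2:
        return solution
    h = np.sqrt((L0**2).sum(axis=1))
    scale = np.where(h > 0, h, 1.0)[:, None]
    A = L0 / scale if kaiser_normalize else L0.copy()
    R = np.eye(m)
    converged = False
    for _ in range(max_iter):
        old = varimax_criterion(A)
        for i in range(m - 1):
            for j in range(i + 1, m):
                x, y = A[:, i], A[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                a_, b_ = u.sum(), v.sum()
                c_ = (u**2 - v**2).sum()
                d_ = 2.0 * (u * v).sum()
                num = d_ - 2.0 * a_ * b_ / p
                den = c_ - (a_**2 - b_**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                cs, sn = np.cos(phi), np.sin(phi)
                G = np.array([[cs, -sn], [sn, cs]])
                A[:, [i, j]] = A[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        if varimax_criterion(A) - old < tol:
            converged = True
            break
    L = L0 @ R
    # reorder by explained variance, then fix signs; fold both into R
    order = np.argsort(-(L**2).sum(axis=0), kind="stable")
    P = np.eye(m)[:, order]
    L = L @ P
    idx = np.argmax(np.abs(L), axis=0)
    signs = np.sign(L[idx, np.arange(m)])
    signs[signs == 0] = 1.0
    L = L * signs
    R = R @ P @ np.diag(signs)
    weights = np.linalg.solve(solution.corr, L)
    return replace(
        solution,
        loadings=L,
        rotation=solution.rotation @ R,
        scoring_weights=weights,
        converged=converged,
    )


def classify_loadings(loadings: np.ndarray) -> np.ndarray:
    """Classify |loading| into weak (<0.4), moderate (0.4-0.6), strong (>0.6)."""
    a = np.abs(np.asarray(loadings, dtype=float))
    out = np.where(a > 0.6, "strong", np.where(a >= 0.4, "moderate", "weak"))
    return out


def score_factors(X, solution: FactorSolution) -> np.ndarray:
    """Regression-method factor scores: standardized X @ (R^-1 @ loadings).

    Columns of ``X`` must match ``solution.variable_names``; scores have
    mean ~0 by construction.
    """
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != list(solution.variable_names):
            missing = set(solution.variable_names) - set(X.columns)
            extra = set(X.columns) - set(solution.variable_names)
            raise ValueError(
                f"column mismatch: missing {sorted(map(str, missing))}, "
                f"unexpected {sorted(map(str, extra))}"
            )
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != len(solution.variable_names):
            raise ValueError(
                f"X has {arr.shape[1]} columns, solution expects {len(solution.variable_names)}"
            )
    Z = (arr - arr.mean(axis=0)) / arr.std(axis=0, ddof=1)
    return Z @ solution.scoring_weights
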