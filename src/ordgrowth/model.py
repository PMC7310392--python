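"""Two-level cumulative-logit growth models for longitudinal ordinal outcomes.

The outcome Y_ti of visit t within subject i takes ordered categories
1..K (here WHO immunological stages, 1 = normal ... 4 = severe).  The
cumulative logits are modelled as

    logit P(Y_ti <= k) = delta^(k) + x*_ti' beta_c^(k) + x_ti' beta
                         + u_0i + u_1i * time_ti,        k = 1..K-1,

where delta^(1) < ... < delta^(K-1) are thresholds, beta are effects shared
across all K-1 logits (the proportional-odds part), beta_c^(k) are
category-specific effects of the non-proportional-odds covariates x*, and
(u_0i, u_1i) is a subject-level random intercept and time slope, jointly
normal with mean zero and covariance D.  A positive coefficient raises
P(Y <= k), i.e. pushes toward better (lower-numbered) stages.

The marginal likelihood integrates the random effects out by adaptive
Gauss-Hermite quadrature (per-subject mode and Laplace curvature, tensor
grid over the Cholesky-transformed effect).  Estimation is by maximum
likelihood (L-BFGS on an unconstrained parameterization: thresholds as a
first value plus log-increments, D through its Cholesky factor with log
diagonal) and, for DIC reporting, by adaptive random-walk Metropolis on the
same parameterization.

Non-proportional parameter vectors that make a cumulative logit
non-monotone in k at some observed covariate pattern would imply a negative
category probability; such vectors receive log-likelihood -inf (soft
rejection) rather than a constrained parameterization.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import norm as _norm

__all__ = [
    "NonMonotoneError",
    "ModelSpec",
    "ParamVector",
    "DesignBundle",
    "build_design",
    "category_probabilities",
    "conditional_loglik",
    "marginal_loglik",
    "fit_mle",
    "fit_mcmc",
    "icc_latent",
    "FitResult",
    "PosteriorFit",
]

LOGISTIC_VARIANCE = math.pi**2 / 3.0

_VAR_FLOOR = 1e-10  # below this a random-effect variance is treated as zero


class NonMonotoneError(ValueError):
    """Cumulative-logit vector not increasing in k: negative category probability."""


# --------------------------------------------------------------------------
# specification and parameters


@dataclass
class ModelSpec:
    """Names and structure of one cumulative-logit growth model.

    ``shared`` lists covariates with one coefficient across all K-1 logits
    (proportional odds); ``npo`` lists covariates with a separate
    coefficient per logit.  ``time_interactions`` generates covariate x time
    columns (appended to the npo block when the base covariate is npo, else
    to the shared block).  Categorical columns are dummy-expanded against
    the reference level in ``categorical_refs`` (default: first level in
    sorted order).
    """

    outcome: str = "stage"
    time: str = "time"
    K: int = 4
    shared: tuple = ()
    npo: tuple = ()
    time_interactions: tuple = ()
    random_effects: tuple = ("intercept", "slope")
    categorical_refs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shared = tuple(self.shared)
        self.npo = tuple(self.npo)
        self.time_interactions = tuple(self.time_interactions)
        self.random_effects = tuple(self.random_effects)
        if self.K < 2:
            raise ValueError("K must be >= 2")
        overlap = set(self.shared) & set(self.npo)
        if overlap:
            raise ValueError(f"covariates in both shared and npo sets: {sorted(overlap)}")
        bad_re = set(self.random_effects) - {"intercept", "slope"}
        if bad_re:
            raise ValueError(f"unknown random effects: {sorted(bad_re)}")
        if "slope" in self.random_effects and "intercept" not in self.random_effects:
            raise ValueError("a random slope requires a random intercept")


@dataclass
class ParamVector:
    """Full parameter state: thresholds, shared and category-specific
    coefficients, and the 2x2 random-effects covariance D.

    ``thresholds`` must be strictly increasing; ``category_coefs`` is
    (n_npo_columns, K-1); ``re_cov`` rows/columns are ordered
    (intercept, slope).
    """

    thresholds: np.ndarray
    shared_coefs: np.ndarray = field(default_factory=lambda: np.zeros(0))
    category_coefs: np.ndarray = field(default_factory=lambda: np.zeros((0, 1)))
    re_cov: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self) -> None:
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        self.shared_coefs = np.atleast_1d(np.asarray(self.shared_coefs, dtype=float))
        self.category_coefs = np.asarray(self.category_coefs, dtype=float)
        if self.category_coefs.ndim == 1:
            self.category_coefs = self.category_coefs.reshape(0, self.K - 1)
        self.re_cov = np.asarray(self.re_cov, dtype=float)

    @property
    def K(self) -> int:
        return len(self.thresholds) + 1

    def validate(self) -> None:
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError("non-finite thresholds")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.category_coefs.size and self.category_coefs.shape[1] != self.K - 1:
            raise ValueError("category_coefs must have K-1 columns")
        D = self.re_cov
        if D.shape != (2, 2) or not np.allclose(D, D.T) or not np.all(np.isfinite(D)):
            raise ValueError("re_cov must be a finite symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(D)) < -1e-8:
            raise ValueError("re_cov must be positive semidefinite")

    @property
    def sigma_v0_sq(self) -> float:
        return float(self.re_cov[0, 0])

    @property
    def sigma_v01(self) -> float:
        return float(self.re_cov[0, 1])

    @property
    def sigma_v1_sq(self) -> float:
        return float(self.re_cov[1, 1])


@dataclass
class DesignBundle:
    """Per-row design arrays with a row -> subject index map."""

    y: np.ndarray  # outcome codes 1..K
    X_shared: np.ndarray  # (n, p)
    X_npo: np.ndarray  # (n, m)
    time: np.ndarray  # (n,)
    subject_idx: np.ndarray  # (n,) values 0..n_subjects-1
    n_subjects: int
    shared_names: list
    npo_names: list
    subject_ids: list
    spec: ModelSpec

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def K(self) -> int:
        return self.spec.K


def _expand_column(data: pd.DataFrame, name: str, refs: dict) -> tuple[np.ndarray, list]:
    col = data[name]
    is_cat = (
        name in refs
        or col.dtype == object
        or isinstance(col.dtype, pd.CategoricalDtype)
        or col.dtype == bool
    )
    if not is_cat:
        return col.to_numpy(dtype=float)[:, None], [name]
    levels = sorted(map(str, pd.unique(col.astype(str).dropna())))
    ref = str(refs.get(name, levels[0]))
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} for {name!r} not among levels {levels}")
    keep = [lv for lv in levels if lv != ref]
    vals = col.astype(str).to_numpy()
    cols = np.column_stack([(vals == lv).astype(float) for lv in keep]) if keep else np.zeros((len(col), 0))
    return cols, [f"{name}[{lv}]" for lv in keep]


def build_design(data: pd.DataFrame, spec: ModelSpec, subject_col: str = "subject_id") -> DesignBundle:
    """Assemble the design bundle for one model from a long-format table.

    Column order is deterministic: shared covariates as listed (interaction
    columns appended), then npo covariates as listed.  Categorical
    covariates are dummy-expanded against their reference level.
    """
    needed = [subject_col, spec.outcome, spec.time, *spec.shared, *spec.npo, *spec.time_interactions]
    missing = [c for c in dict.fromkeys(needed) if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    y_raw = data[spec.outcome]
    if y_raw.isna().any():
        raise ValueError("missing outcome values")
    y = y_raw.to_numpy(dtype=int)
    if np.any((y < 1) | (y > spec.K)):
        bad = sorted(set(y) - set(range(1, spec.K + 1)))
        raise ValueError(f"outcome codes outside 1..{spec.K}: {bad}")
    t = data[spec.time].to_numpy(dtype=float)
    refs = spec.categorical_refs

    def block(names: tuple, with_time: tuple) -> tuple[np.ndarray, list]:
        mats, labels = [], []
        for nm in names:
            m_, lab = _expand_column(data, nm, refs)
            mats.append(m_)
            labels.extend(lab)
        for nm in with_time:
            m_, lab = _expand_column(data, nm, refs)
            mats.append(m_ * t[:, None])
            labels.extend(f"{x}:{spec.time}" for x in lab)
        if mats:
            return np.hstack(mats), labels
        return np.zeros((len(data), 0)), labels

    inter_npo = tuple(nm for nm in spec.time_interactions if nm in spec.npo)
    inter_shared = tuple(nm for nm in spec.time_interactions if nm not in spec.npo)
    Xs, shared_names = block(spec.shared, inter_shared)
    Xn, npo_names = block(spec.npo, inter_npo)
    codes, uniques = pd.factorize(data[subject_col], sort=False)
    return DesignBundle(
        y=y,
        X_shared=np.ascontiguousarray(Xs),
        X_npo=np.ascontiguousarray(Xn),
        time=t,
        subject_idx=codes.astype(np.int64),
        n_subjects=len(uniques),
        shared_names=shared_names,
        npo_names=npo_names,
        subject_ids=list(uniques),
        spec=spec,
    )


# --------------------------------------------------------------------------
# probabilities and likelihood


def _cumulative_logits(params: ParamVector, x_shared, x_npo, time, u) -> np.ndarray:
    eta = params.thresholds.copy()
    if params.shared_coefs.size:
        eta = eta + float(np.dot(np.atleast_1d(x_shared), params.shared_coefs))
    if params.category_coefs.size:
        eta = eta + np.atleast_1d(x_npo) @ params.category_coefs
    return eta + u[0] + u[1] * time


def category_probabilities(params: ParamVector, x_shared=(), x_npo=(), time: float = 0.0, u=(0.0, 0.0)) -> np.ndarray:
    """Category probabilities (p_1..p_K) for one visit row.

    p_k = P(Y<=k) - P(Y<=k-1) with P(Y<=0)=0, P(Y<=K)=1.  Raises
    :class:`NonMonotoneError` if the implied cumulative probabilities are
    not monotone in k (possible under non-proportional odds).
    """
    eta = _cumulative_logits(params, x_shared, x_npo, time, u)
    cum = np.concatenate([[0.0], expit(eta), [1.0]])
    p = np.diff(cum)
    if np.any(p < 0):
        raise NonMonotoneError(
            f"non-monotone cumulative probabilities for covariate pattern "
            f"x_shared={np.atleast_1d(x_shared)}, x_npo={np.atleast_1d(x_npo)}, time={time}"
        )
    return p


def conditional_loglik(params: ParamVector, rows: pd.DataFrame | DesignBundle, u=(0.0, 0.0), spec: ModelSpec | None = None) -> float:
    """Log-likelihood of one subject's visits given its random effects.

    Visits are conditionally independent given u, so this is the sum of log
    category probabilities.  ``rows`` may be a DesignBundle (all rows used)
    or a long-format frame with ``spec`` supplied.
    """
    if isinstance(rows, pd.DataFrame):
        if spec is None:
            raise ValueError("spec required when rows is a DataFrame")
        rows = build_design(rows.assign(**{"__s": 0}), spec, subject_col="__s")
    total = 0.0
    for i in range(rows.n_rows):
        p = category_probabilities(
            params, rows.X_shared[i], rows.X_npo[i], rows.time[i], u
        )
        pk = p[rows.y[i] - 1]
        if pk <= 0:
            return -np.inf
        total += math.log(pk)
    return total


def _log_expit_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(expit(a) - expit(b)) for a >= b, stable in both tails.

    Fast path: direct difference of expits (accurate whenever the
    difference is not tiny); elements whose probability underflows are
    recomputed with the tail-stable factorization
    log p = log_expit(a) + log_expit(-b) + log1p(-exp(b-a)).
    """
    a, b = np.broadcast_arrays(a, b)
    p = expit(a) - expit(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(p)
    small = p < 1e-8  # below this the direct difference loses precision
    if np.any(small):
        asml, bsml = a[small], b[small]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            d = np.minimum(bsml - asml, -0.0)
            out[small] = log_expit(asml) + log_expit(-bsml) + np.log1p(-np.exp(d))
    return out


class _Engine:
    """Vectorized marginal-likelihood evaluator for one design bundle.

    Keeps per-subject posterior modes as warm starts across calls, which
    makes finite-difference derivatives of the marginal likelihood cheap
    and smooth.
    """

    def __init__(self, bundle: DesignBundle, quad_order: int = 9):
        self.b = bundle
        self.quad_order = int(quad_order)
        if self.quad_order < 1:
            raise ValueError("quad_order must be >= 1")
        n, K = bundle.n_rows, bundle.K
        y = bundle.y
        rows = np.arange(n)
        # per-row upper/lower threshold indices; +/-inf when y==K / y==1
        self._iu = np.clip(y - 1, 0, K - 2)
        self._il = np.clip(y - 2, 0, K - 2)
        self._has_up = y < K
        self._has_lo = y > 1
        self._rows = rows
        self.modes = np.zeros((bundle.n_subjects, 2))
        x, w = np.polynomial.hermite.hermgauss(self.quad_order)
        self._gh_x, self._gh_logw = x, np.log(w)
        # subject-aggregation operator: (n_subjects x n_rows) @ per-row matrix
        self._S = sparse.csr_matrix(
            (np.ones(n), (bundle.subject_idx, np.arange(n))),
            shape=(bundle.n_subjects, n),
        )

    # -- fixed (covariate) part of the cumulative logits ------------------
    def _eta_bounds(self, params: ParamVector) -> tuple[np.ndarray, np.ndarray] | None:
        b = self.b
        eta = np.tile(params.thresholds, (b.n_rows, 1))
        if params.shared_coefs.size:
            eta += (b.X_shared @ params.shared_coefs)[:, None]
        if params.category_coefs.size:
            eta += b.X_npo @ params.category_coefs
        if eta.shape[1] > 1 and np.any(np.diff(eta, axis=1) < 0):
            return None  # non-monotone at some observed pattern
        up = np.where(self._has_up, eta[self._rows, self._iu], np.inf)
        lo = np.where(self._has_lo, eta[self._rows, self._il], -np.inf)
        return up, lo

    def _row_logp(self, up, lo, shift):
        return _log_expit_diff(up + shift, lo + shift)

    def _row_derivs(self, up, lo, shift):
        """Per-row (logp, d logp/ds, d2 logp/ds2) w.r.t. the common shift s.

        The score g and curvature h of an ordinal-logit category
        log-probability are bounded (|g| <= 1, -0.5 <= h <= 0); where the
        probability underflows the direct ratios are replaced by their
        asymptotic limits: deep upper tail (-1, 0), deep lower tail (1, 0),
        vanishing threshold gap (1-2F, -2f).
        """
        a, c = up + shift, lo + shift
        logp = _log_expit_diff(a, c)
        Fu, Fl = expit(a), expit(c)
        p = np.exp(logp)
        safe = p > 1e-10
        p_safe = np.where(safe, p, 1.0)
        fu = np.where(np.isfinite(a), Fu * (1 - Fu), 0.0)
        fl = np.where(np.isfinite(c), Fl * (1 - Fl), 0.0)
        g = (fu - fl) / p_safe
        h = (fu * (1 - 2 * Fu) - fl * (1 - 2 * Fl)) / p_safe - g * g
        if not np.all(safe):
            mid = 0.5 * (np.where(np.isfinite(a), a, 0.0) + np.where(np.isfinite(c), c, 0.0))
            Fm = expit(mid)
            fm = Fm * (1 - Fm)
            g_lim = np.where(c > 20.0, -1.0, np.where(a < -20.0, 1.0, 1.0 - 2.0 * Fm))
            h_lim = np.where((c > 20.0) | (a < -20.0), 0.0, -2.0 * fm)
            g = np.where(safe, g, g_lim)
            h = np.where(safe, h, h_lim)
        return logp, g, h

    # -- subject aggregation ----------------------------------------------
    def _agg(self, vals):
        return np.bincount(self.b.subject_idx, weights=vals, minlength=self.b.n_subjects)

    def _re_dim(self, D: np.ndarray) -> int:
        if D[0, 0] < _VAR_FLOOR:
            return 0
        if D[1, 1] < _VAR_FLOOR:
            return 1
        return 2

    def subject_logliks(self, params: ParamVector) -> np.ndarray:
        """Per-subject log marginal likelihood contributions."""
        bounds = self._eta_bounds(params)
        if bounds is None:
            return np.full(self.b.n_subjects, -np.inf)
        up, lo = bounds
        D = params.re_cov
        d = self._re_dim(D)
        if d == 0:
            return self._agg(self._row_logp(up, lo, 0.0))
        if d == 1:
            return self._marginal_1d(up, lo, D[0, 0])
        return self._marginal_2d(up, lo, D)

    def loglik(self, params: ParamVector) -> float:
        return float(np.sum(self.subject_logliks(params)))

    # -- 1-D (random intercept, or rank-one intercept+slope) ---------------
    def _marginal_1d(self, up, lo, var0: float, z: np.ndarray | None = None) -> np.ndarray:
        b = self.b
        prec = 1.0 / var0
        zz = np.ones(b.n_rows) if z is None else z

        def newton(u):
            u_prev = u
            obj_prev = None
            grad = np.array([np.inf])
            for _ in range(100):
                s = u[b.subject_idx] * zz
                logp, g, h = self._row_derivs(up, lo, s)
                grad = self._agg(g * zz) - prec * u
                hess = self._agg(h * zz * zz) - prec
                step = grad / np.maximum(-hess, 1e-12)
                obj = self._agg(logp) - 0.5 * prec * u * u
                if obj_prev is not None:
                    worse = obj < obj_prev - 1e-12
                    # step-halve subjects that worsened at the previous update
                    if np.any(worse):
                        u = np.where(worse, u_prev + 0.5 * (u - u_prev), u)
                        continue
                if np.max(np.abs(grad)) < 1e-9:
                    return u, True
                u_prev, obj_prev = u.copy(), obj
                u = u + np.clip(step, -5.0, 5.0)
            return u, np.max(np.abs(grad)) < 1e-6

        u, ok = newton(self.modes[:, 0].copy())
        if not ok:
            u, _ = newton(np.zeros(b.n_subjects))  # cold restart: log-concave target
        self.modes[:, 0] = u
        hess_full = self._agg(self._row_derivs(up, lo, u[b.subject_idx] * zz)[2] * zz * zz) - prec
        sigma = 1.0 / np.maximum(-hess_full, 1e-12)
        sd = np.sqrt(sigma)
        xs, logw = self._gh_x, self._gh_logw
        uq = u[:, None] + math.sqrt(2.0) * sd[:, None] * xs[None, :]  # (N, Q)
        shift = uq[b.subject_idx] * zz[:, None]  # (n, Q)
        logp = self._row_logp(up[:, None], lo[:, None], shift)
        ll = self._S @ logp  # (N, Q)
        logphi = -0.5 * math.log(2 * math.pi * var0) - 0.5 * uq * uq / var0
        terms = (logw + xs * xs)[None, :] + ll + logphi
        return logsumexp(terms, axis=1) + 0.5 * math.log(2.0) + np.log(sd)

    # -- 2-D (random intercept + slope) ------------------------------------
    def _marginal_2d(self, up, lo, D: np.ndarray) -> np.ndarray:
        """Adaptive tensor-grid quadrature in prior-whitened coordinates.

        With L the lower Cholesky factor of D and u = L v, the prior on v
        is standard bivariate normal and the per-row shift is
        v0*z0 + v1*z1 with z0 = L00 + L10*t, z1 = L11*t.  The posterior
        precision in v is I minus a negative-semidefinite likelihood
        curvature, so the Newton system is always well conditioned, even
        for nearly singular D (slope variance ~ 0 or correlation ~ +/-1).
        """
        b = self.b
        t = b.time
        L00 = math.sqrt(D[0, 0])
        L10 = D[0, 1] / L00
        L11 = math.sqrt(max(D[1, 1] - L10 * L10, 0.0))
        z0 = L00 + L10 * t
        z1 = L11 * t

        def newton(v):
            obj_prev = None
            v_prev = v.copy()
            gnorm = np.inf
            for _ in range(100):
                s = v[b.subject_idx, 0] * z0 + v[b.subject_idx, 1] * z1
                logp, g, h = self._row_derivs(up, lo, s)
                gr0 = self._agg(g * z0) - v[:, 0]
                gr1 = self._agg(g * z1) - v[:, 1]
                obj = self._agg(logp) - 0.5 * (v[:, 0] ** 2 + v[:, 1] ** 2)
                if obj_prev is not None:
                    worse = obj < obj_prev - 1e-12
                    if np.any(worse):
                        v[worse] = v_prev[worse] + 0.5 * (v[worse] - v_prev[worse])
                        continue
                gnorm = max(np.max(np.abs(gr0)), np.max(np.abs(gr1)))
                if gnorm < 1e-9:
                    return v, True
                # positive-definite system M = I - H_v, H_v = likelihood curvature
                M00 = 1.0 - self._agg(h * z0 * z0)
                M01 = -self._agg(h * z0 * z1)
                M11 = 1.0 - self._agg(h * z1 * z1)
                mdet = M00 * M11 - M01 * M01  # >= 1 by construction
                d0 = (M11 * gr0 - M01 * gr1) / mdet
                d1 = (-M01 * gr0 + M00 * gr1) / mdet
                step = np.minimum(1.0, 20.0 / np.maximum(np.hypot(d0, d1), 1e-12))
                v_prev, obj_prev = v.copy(), obj
                v = v + np.column_stack([d0 * step, d1 * step])
            return v, bool(gnorm < 1e-6)

        v, ok = newton(self.modes.copy())
        if not ok:
            v, _ = newton(np.zeros((b.n_subjects, 2)))  # cold restart: log-concave
        self.modes = v.copy()
        # Laplace curvature at the mode -> Sigma_v = M^-1 and its Cholesky
        s = v[b.subject_idx, 0] * z0 + v[b.subject_idx, 1] * z1
        h = self._row_derivs(up, lo, s)[2]
        M00 = 1.0 - self._agg(h * z0 * z0)
        M01 = -self._agg(h * z0 * z1)
        M11 = 1.0 - self._agg(h * z1 * z1)
        mdet = M00 * M11 - M01 * M01
        S00, S01, S11 = M11 / mdet, -M01 / mdet, M00 / mdet
        C00 = np.sqrt(S00)
        C10 = S01 / C00
        C11 = np.sqrt(np.maximum(S11 - C10 * C10, 1e-300))
        xs, logw = self._gh_x, self._gh_logw
        Q = len(xs)
        x1 = np.repeat(xs, Q)
        x2 = np.tile(xs, Q)
        lw = np.repeat(logw, Q) + np.tile(logw, Q)
        sq = x1 * x1 + x2 * x2
        r2 = math.sqrt(2.0)
        v0 = v[:, 0:1] + r2 * C00[:, None] * x1[None, :]  # (N, Q^2)
        v1 = v[:, 1:2] + r2 * (C10[:, None] * x1[None, :] + C11[:, None] * x2[None, :])
        shift = v0[b.subject_idx] * z0[:, None] + v1[b.subject_idx] * z1[:, None]  # (n, Q^2)
        logp = self._row_logp(up[:, None], lo[:, None], shift)
        ll = self._S @ logp  # (N, Q^2)
        terms = (lw + sq)[None, :] + ll - math.log(2 * math.pi) - 0.5 * (v0 * v0 + v1 * v1)
        return logsumexp(terms, axis=1) + math.log(2.0) + np.log(C00 * C11)


def marginal_loglik(params: ParamVector, bundle: DesignBundle, quad_order: int = 9) -> float:
    """Marginal log-likelihood with random effects integrated out.

    Sum over subjects of log int exp(conditional_loglik(u)) dN(u; 0, D),
    by adaptive Gauss-Hermite quadrature (``quad_order`` nodes per
    dimension).  A degenerate slope variance collapses to 1-D quadrature;
    D = 0 collapses to the conditional likelihood at u = 0.
    """
    params.validate()
    return _Engine(bundle, quad_order).loglik(params)


def icc_latent(sigma_v0_sq: float) -> float:
    """Latent-scale intraclass correlation sigma_v0^2/(sigma_v0^2 + pi^2/3).

    The level-1 variance of the cumulative-logit model is the standard
    logistic variance pi^2/3.
    """
    if not np.isfinite(sigma_v0_sq) or sigma_v0_sq < 0:
        raise ValueError(f"intercept variance must be non-negative, got {sigma_v0_sq!r}")
    return float(sigma_v0_sq / (sigma_v0_sq + LOGISTIC_VARIANCE))


# --------------------------------------------------------------------------
# unconstrained parameterization


class _Parameterization:
    """Bijection between ParamVector and an unconstrained vector theta.

    Thresholds are stored as delta^(1) plus log-increments; D through its
    Cholesky factor [[e^a, 0], [b, e^c]] (intercept-only: just a; no random
    effects: nothing).
    """

    def __init__(self, bundle: DesignBundle):
        spec = bundle.spec
        self.K = spec.K
        self.p = bundle.X_shared.shape[1]
        self.m = bundle.X_npo.shape[1]
        self.re = (
            "full"
            if "slope" in spec.random_effects
            else ("intercept" if "intercept" in spec.random_effects else "none")
        )
        self.n_re = {"none": 0, "intercept": 1, "full": 3}[self.re]
        self.n_params = (self.K - 1) + self.p + self.m * (self.K - 1) + self.n_re
        self.bundle = bundle

    def pack(self, pv: ParamVector) -> np.ndarray:
        K = self.K
        th = pv.thresholds
        parts = [np.concatenate([[th[0]], np.log(np.diff(th))]) if K > 2 else th[:1]]
        parts.append(pv.shared_coefs)
        parts.append(pv.category_coefs.ravel())
        if self.re == "intercept":
            parts.append([0.5 * math.log(max(pv.re_cov[0, 0], 1e-12))])
        elif self.re == "full":
            L = np.linalg.cholesky(pv.re_cov + 1e-12 * np.eye(2))
            parts.append([math.log(L[0, 0]), L[1, 0], math.log(L[1, 1])])
        return np.concatenate([np.asarray(x, dtype=float).ravel() for x in parts])

    def unpack(self, theta: np.ndarray) -> ParamVector:
        # clamp far outside any meaningful range: keeps exp() finite for
        # extreme MCMC proposals (which are then rejected on likelihood)
        theta = np.clip(theta, -50.0, 50.0)
        K, p, m = self.K, self.p, self.m
        i = 0
        th = np.empty(K - 1)
        th[0] = theta[0]
        if K > 2:
            th[1:] = th[0] + np.cumsum(np.exp(theta[1 : K - 1]))
        i = K - 1
        beta = theta[i : i + p]
        i += p
        Bc = theta[i : i + m * (K - 1)].reshape(m, K - 1)
        i += m * (K - 1)
        D = np.zeros((2, 2))
        if self.re == "intercept":
            D[0, 0] = math.exp(2.0 * theta[i])
        elif self.re == "full":
            a, b_, c = theta[i], theta[i + 1], theta[i + 2]
            L = np.array([[math.exp(a), 0.0], [b_, math.exp(c)]])
            D = L @ L.T
        return ParamVector(thresholds=th, shared_coefs=beta, category_coefs=Bc, re_cov=D)

    # reporting scale: thresholds, coefficients, then variance components
    def report(self, theta: np.ndarray) -> np.ndarray:
        pv = self.unpack(theta)
        parts = [pv.thresholds, pv.shared_coefs, pv.category_coefs.ravel()]
        if self.re == "intercept":
            parts.append([pv.re_cov[0, 0]])
        elif self.re == "full":
            parts.append([pv.re_cov[0, 0], pv.re_cov[0, 1], pv.re_cov[1, 1]])
        return np.concatenate([np.asarray(x, dtype=float).ravel() for x in parts])

    def report_names(self) -> tuple[list, list, list]:
        b = self.bundle
        names, kinds, logits = [], [], []
        for k in range(1, self.K):
            names.append(f"threshold_{k}")
            kinds.append("threshold")
            logits.append(k)
        for nm in b.shared_names:
            names.append(nm)
            kinds.append("shared")
            logits.append(0)
        for nm in b.npo_names:
            for k in range(1, self.K):
                names.append(f"{nm}|logit{k}")
                kinds.append("npo")
                logits.append(k)
        if self.re == "intercept":
            names += ["var_intercept"]
            kinds += ["random"]
            logits += [0]
        elif self.re == "full":
            names += ["var_intercept", "cov_intercept_slope", "var_slope"]
            kinds += ["random"] * 3
            logits += [0, 0, 0]
        return names, kinds, logits


def _default_start(bundle: DesignBundle, parzn: _Parameterization) -> ParamVector:
    K = bundle.K
    counts = np.bincount(bundle.y, minlength=K + 1)[1:]
    if np.any(counts == 0):
        missing = [k + 1 for k in range(K) if counts[k] == 0]
        raise ValueError(
            f"outcome categories never observed: {missing}; merge categories before fitting"
        )
    cum = np.cumsum(counts)[:-1] / counts.sum()
    th = np.log(cum / (1 - cum))
    D = np.diag([1.0, 0.01])
    return ParamVector(
        thresholds=th,
        shared_coefs=np.zeros(parzn.p),
        category_coefs=np.zeros((parzn.m, K - 1)),
        re_cov=D,
    )


# --------------------------------------------------------------------------
# maximum likelihood


@dataclass
class FitResult:
    """Maximum-likelihood fit of one cumulative-logit growth model."""

    params: ParamVector
    table: pd.DataFrame  # name, kind, logit, estimate, se, ci_low, ci_high, p_value
    minus2loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    icc: float | None
    quad_order: int
    spec: ModelSpec
    theta: np.ndarray
    cov_theta: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return len(self.theta)


def _fd_hessian(fun, x: np.ndarray, rel_h: float = 1e-3) -> np.ndarray:
    n = len(x)
    h = rel_h * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _fd_jacobian(fun, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    f0 = np.asarray(fun(x))
    J = np.empty((len(f0), len(x)))
    for i in range(len(x)):
        xp = x.copy()
        xp[i] += h
        J[:, i] = (np.asarray(fun(xp)) - f0) / h
    return J


_PENALTY = 1e10


def fit_mle(
    bundle: DesignBundle,
    quad_order: int = 9,
    init: ParamVector | np.ndarray | None = None,
    maxiter: int = 500,
    compute_se: bool = True,
    ftol: float = 1e-11,
    gtol: float = 1e-6,
) -> FitResult:
    """Maximum marginal likelihood by L-BFGS over the unconstrained
    parameterization, standard errors from the inverse numerical Hessian.

    Wald 95% intervals are on the logit scale (variance components on their
    own scale via the delta method).  Non-convergence yields a flagged
    result rather than an exception.
    """
    parzn = _Parameterization(bundle)
    engine = _Engine(bundle, quad_order)
    if init is None:
        theta0 = parzn.pack(_default_start(bundle, parzn))
    elif isinstance(init, ParamVector):
        theta0 = parzn.pack(init)
    else:
        theta0 = np.asarray(init, dtype=float).copy()

    best = {"f": np.inf, "theta": None}

    def negll(theta: np.ndarray) -> float:
        pv = parzn.unpack(theta)
        ll = engine.loglik(pv)
        if not np.isfinite(ll):
            return _PENALTY
        if -ll < best["f"]:
            best["f"], best["theta"] = -ll, theta.copy()
        return -ll

    def negll_grad(theta: np.ndarray) -> np.ndarray:
        # forward differences from a fixed snapshot of the per-subject
        # modes, so every perturbed evaluation shares the same warm start
        # and the gradient is smooth in theta
        f0 = negll(theta)
        snapshot = engine.modes.copy()
        g = np.empty_like(theta)
        for i in range(len(theta)):
            h = 1e-6 * max(1.0, abs(theta[i]))
            tp = theta.copy()
            tp[i] += h
            engine.modes = snapshot.copy()
            g[i] = (negll(tp) - f0) / h
        engine.modes = snapshot
        return g

    # loose box bounds: keep the log-scale parameters (threshold increments,
    # Cholesky log-diagonals) from numerical runaway, far wider than any
    # scientifically meaningful estimate
    n_fixed = (parzn.K - 1) + parzn.p + parzn.m * (parzn.K - 1)
    lb = np.full(parzn.n_params, -50.0)
    ub = np.full(parzn.n_params, 50.0)
    if parzn.K > 2:
        lb[1 : parzn.K - 1] = -20.0
        ub[1 : parzn.K - 1] = 10.0
    if parzn.re == "intercept":
        lb[n_fixed], ub[n_fixed] = -7.0, 4.0
    elif parzn.re == "full":
        lb[n_fixed], ub[n_fixed] = -7.0, 4.0  # log sd of intercept
        lb[n_fixed + 1], ub[n_fixed + 1] = -20.0, 20.0
        lb[n_fixed + 2], ub[n_fixed + 2] = -7.0, 4.0
    res = optimize.minimize(
        negll,
        np.clip(theta0, lb + 1e-6, ub - 1e-6),
        jac=negll_grad,
        method="L-BFGS-B",
        bounds=list(zip(lb, ub)),
        options={"maxiter": maxiter, "ftol": ftol, "gtol": gtol},
    )
    # validate the optimizer's endpoint against the best point seen, both
    # re-evaluated from a cold mode state (guards against any residual
    # warm-start path dependence)
    candidates = [res.x] + ([best["theta"]] if best["theta"] is not None else [])
    f_final = []
    for cand in candidates:
        engine.modes[:] = 0.0
        f_final.append(negll(cand))
    pick = int(np.argmin(f_final))
    theta = np.asarray(candidates[pick], dtype=float)
    fun_final = f_final[pick]
    pv = parzn.unpack(theta)
    stuck_invalid = fun_final >= 0.5 * _PENALTY
    names, kinds, logits = parzn.report_names()
    est = parzn.report(theta)
    se = np.full(len(est), np.nan)
    cov_theta = None
    if compute_se:
        H = _fd_hessian(negll, theta)
        cov_theta = np.linalg.pinv(0.5 * (H + H.T))
        J = _fd_jacobian(parzn.report, theta)
        cov_rep = J @ cov_theta @ J.T
        se = np.sqrt(np.clip(np.diag(cov_rep), 0.0, None))
    z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    pvals = 2.0 * _norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "name": names,
            "kind": kinds,
            "logit": logits,
            "estimate": est,
            "se": se,
            "ci_low": est - 1.959963984540054 * se,
            "ci_high": est + 1.959963984540054 * se,
            "p_value": pvals,
        }
    )
    icc = icc_latent(pv.sigma_v0_sq) if parzn.re != "none" else None
    return FitResult(
        params=pv,
        table=table,
        minus2loglik=2.0 * fun_final,
        converged=bool(res.success) and not stuck_invalid,
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        icc=icc,
        quad_order=quad_order,
        spec=bundle.spec,
        theta=theta,
        cov_theta=cov_theta,
    )


def nested_init(fit_po: FitResult, bundle_npo: DesignBundle) -> ParamVector:
    """Starting values for an NPO fit from the nested PO solution.

    Thresholds, shared coefficients and D are carried over; each npo design
    column's category-specific coefficients start at the PO (shared)
    estimate replicated across the K-1 logits.  Starting the general fit
    here guarantees its likelihood can only improve on the restricted one,
    so the LR statistic is non-negative up to optimizer tolerance.
    """
    po = fit_po.params
    shared_tab = fit_po.table[fit_po.table["kind"] == "shared"]
    lut = dict(zip(shared_tab["name"], shared_tab["estimate"]))
    missing = [nm for nm in (*bundle_npo.shared_names, *bundle_npo.npo_names) if nm not in lut]
    if missing:
        raise ValueError(f"PO fit lacks coefficients for: {missing}; models are not nested")
    K = bundle_npo.K
    beta = np.array([lut[nm] for nm in bundle_npo.shared_names])
    Bc = np.array([[lut[nm]] * (K - 1) for nm in bundle_npo.npo_names]).reshape(
        len(bundle_npo.npo_names), K - 1
    )
    return ParamVector(
        thresholds=po.thresholds.copy(),
        shared_coefs=beta,
        category_coefs=Bc,
        re_cov=po.re_cov.copy(),
    )


# --------------------------------------------------------------------------
# MCMC (for DIC)


@dataclass
class PosteriorFit:
    """Posterior sample from adaptive random-walk Metropolis.

    Deviance is -2 x marginal log-likelihood (random effects integrated
    out); dic = dbar + pD with pD = dbar - deviance at the posterior mean.
    """

    draws: pd.DataFrame  # reporting-scale draws, one column per parameter
    theta_draws: np.ndarray
    logliks: np.ndarray
    acceptance_rate: float
    dbar: float
    p_d: float
    dic: float
    median_params: ParamVector
    table: pd.DataFrame  # name, kind, logit, estimate (median), ci_low, ci_high
    converged: bool
    warnings: list
    spec: ModelSpec
    icc: float | None


def _log_prior(theta: np.ndarray, parzn: _Parameterization, scale_coef: float = 10.0, scale_sd: float = 5.0) -> float:
    K, p, m = parzn.K, parzn.p, parzn.m
    n_fixed = (K - 1) + p + m * (K - 1)
    lp = float(np.sum(_norm.logpdf(theta[:n_fixed], 0.0, scale_coef)))
    if parzn.re == "intercept":
        a = theta[n_fixed]
        sd0 = math.exp(a)
        lp += _norm.logpdf(sd0, 0.0, scale_sd) + math.log(2.0) + a  # half-normal + Jacobian
    elif parzn.re == "full":
        a, b_, c = theta[n_fixed : n_fixed + 3]
        sd0 = math.exp(a)
        sd1 = math.hypot(b_, math.exp(c))
        # half-normal on both SDs, uniform on the correlation, log-Jacobian
        lp += _norm.logpdf(sd0, 0.0, scale_sd) + math.log(2.0)
        lp += _norm.logpdf(sd1, 0.0, scale_sd) + math.log(2.0) - math.log(2.0)
        lp += a + 2.0 * c - 2.0 * math.log(sd1)
    return lp


def fit_mcmc(
    bundle: DesignBundle,
    quad_order: int = 5,
    n_iter: int = 3000,
    burn: int = 1000,
    seed: int = 0,
    init: FitResult | ParamVector | np.ndarray | None = None,
    prior_scale_coef: float = 10.0,
    prior_scale_sd: float = 5.0,
) -> PosteriorFit:
    """Adaptive random-walk Metropolis over the unconstrained parameters.

    The target is marginal log-likelihood plus log prior (diffuse normal on
    coefficients and threshold increments, half-normal on random-effect
    SDs, uniform on their correlation).  The proposal scale adapts toward
    ~30% acceptance during burn-in; an acceptance rate outside [0.1, 0.6]
    after adaptation is recorded as a warning, not an error.
    """
    parzn = _Parameterization(bundle)
    engine = _Engine(bundle, quad_order)
    rng = np.random.default_rng(seed)
    if init is None:
        theta = parzn.pack(_default_start(bundle, parzn))
    elif isinstance(init, FitResult):
        theta = init.theta.copy()
    elif isinstance(init, ParamVector):
        theta = parzn.pack(init)
    else:
        theta = np.asarray(init, dtype=float).copy()
    n = len(theta)
    # per-coordinate proposal scales: MLE Wald SDs when available
    sd_vec = np.ones(n)
    if isinstance(init, FitResult) and init.cov_theta is not None:
        sd_vec = np.sqrt(np.clip(np.diag(init.cov_theta), 1e-6, None))

    def logpost(th):
        ll = engine.loglik(parzn.unpack(th))
        if not np.isfinite(ll):
            return -np.inf, -np.inf
        return ll + _log_prior(th, parzn, prior_scale_coef, prior_scale_sd), ll

    lp, ll = logpost(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")
    log_step = math.log(2.4 / math.sqrt(n))
    accepted = 0
    accepted_post = 0
    kept_theta = np.empty((n_iter - burn, n))
    kept_ll = np.empty(n_iter - burn)
    target = 0.3
    for it in range(n_iter):
        prop = theta + math.exp(log_step) * sd_vec * rng.standard_normal(n)
        lp_p, ll_p = logpost(prop)
        if np.isfinite(lp_p) and math.log(rng.uniform()) < lp_p - lp:
            theta, lp, ll = prop, lp_p, ll_p
            accepted += 1
            if it >= burn:
                accepted_post += 1
        if it < burn:
            acc_rate = accepted / (it + 1)
            log_step += (acc_rate - target) / math.sqrt(it + 1)
        if it >= burn:
            kept_theta[it - burn] = theta
            kept_ll[it - burn] = ll
        if not np.isfinite(lp):
            raise RuntimeError(f"posterior became non-finite at iteration {it}")
    n_kept = n_iter - burn
    acc = accepted_post / max(n_kept, 1)
    warns = []
    if not 0.1 <= acc <= 0.6:
        warns.append(f"acceptance rate {acc:.3f} outside [0.1, 0.6] after adaptation")
    dev = -2.0 * kept_ll
    dbar = float(dev.mean())
    theta_mean = kept_theta.mean(axis=0)
    dev_at_mean = -2.0 * engine.loglik(parzn.unpack(theta_mean))
    p_d = dbar - float(dev_at_mean)
    dic = dbar + p_d
    rep = np.array([parzn.report(th) for th in kept_theta])
    names, kinds, logits = parzn.report_names()
    draws = pd.DataFrame(rep, columns=names)
    med = np.median(rep, axis=0)
    lo_q, hi_q = np.percentile(rep, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {"name": names, "kind": kinds, "logit": logits, "estimate": med, "ci_low": lo_q, "ci_high": hi_q}
    )
    # two-sided posterior tail probability, for star bands in reports
    pos = (rep > 0).mean(axis=0)
    table["p_value"] = 2.0 * np.minimum(pos, 1.0 - pos)
    median_theta = np.median(kept_theta, axis=0)
    median_params = parzn.unpack(median_theta)
    icc = icc_latent(median_params.sigma_v0_sq) if parzn.re != "none" else None
    return PosteriorFit(
        draws=draws,
        theta_draws=kept_theta,
        logliks=kept_ll,
        acceptance_rate=acc,
        dbar=dbar,
        p_d=p_d,
        dic=dic,
        median_params=median_params,
        table=table,
        converged=0.1 <= acc <= 0.6,
        warnings=warns,
        spec=bundle.spec,
        icc=icc,
    )
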