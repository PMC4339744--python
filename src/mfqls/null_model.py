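"""Per-phenotype null linear mixed model and phenotype adjustment.

For each phenotype ``q`` the null model is

    y = Z a + B + E,   var(B) = s2_B * Phi,   var(E) = s2_E * I,

fitted by restricted maximum likelihood. The REML problem is solved by a
one-dimensional profile over the heritability ratio h = s2_B/(s2_B + s2_E)
on the eigenbasis of Phi, which shares its stationary points with the usual
average-information iteration but cannot diverge. Dichotomous phenotypes are
treated as quantitative for this step.

The adjusted phenotype matrix ``T`` subtracts either the BLUP-based offset
(mixed-model fitted values including the predicted polygenic effect) or, for
dichotomous phenotypes under ascertained sampling, the disease prevalence.
Rows with missing phenotypes are excluded from the fit and then set to
exactly zero in ``T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from mfqls.exceptions import DataError, DegenerateModelError
from mfqls.linalg import PhiOps, as_phi_ops

__all__ = [
    "PhenotypeMatrix",
    "CovariateMatrix",
    "NullModelFit",
    "fit_null_reml",
    "fit_null_models",
    "blup_offset",
    "prevalence_offset",
    "zero_missing_phenotypes",
]

QUANTITATIVE = "quantitative"
DICHOTOMOUS = "dichotomous"

_H_MAX = 1.0 - 1e-6
_H_TOL = 1e-8


@dataclass
class PhenotypeMatrix:
    """N x Q phenotype matrix with missingness encoded as NaN."""

    values: np.ndarray = field(repr=False)
    names: list[str] | None = None
    kinds: list[str] | None = None
    prevalence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise DataError("phenotype matrix must be 2-dimensional")
        n, q = self.values.shape
        if self.names is None:
            self.names = [f"P{j + 1}" for j in range(q)]
        if self.kinds is None:
            self.kinds = [self._detect_kind(self.values[:, j]) for j in range(q)]
        for j, kind in enumerate(self.kinds):
            if kind == DICHOTOMOUS:
                col = self.values[:, j]
                obs = col[~np.isnan(col)]
                if not np.isin(obs, (0.0, 1.0)).all():
                    raise DataError(
                        f"dichotomous phenotype {self.names[j]!r} has values "
                        "outside {0, 1}"
                    )
        if self.prevalence is not None:
            self.prevalence = np.asarray(self.prevalence, dtype=float)
            if np.any((self.prevalence <= 0) | (self.prevalence >= 1)):
                raise DataError("prevalence must lie in (0, 1)")

    @staticmethod
    def _detect_kind(col: np.ndarray) -> str:
        obs = col[~np.isnan(col)]
        distinct = np.unique(obs)
        if len(distinct) <= 2 and np.isin(distinct, (0.0, 1.0)).all():
            return DICHOTOMOUS
        return QUANTITATIVE

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class CovariateMatrix:
    """N x c covariate matrix whose first column is the intercept."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.allclose(self.values[:, 0], 1.0):
            raise DataError("first covariate column must be the intercept (all 1)")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise DataError("covariate matrix is rank deficient")

    @classmethod
    def intercept_only(cls, n: int) -> "CovariateMatrix":
        return cls(np.ones((n, 1)))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def c(self) -> int:
        return self.values.shape[1]


@dataclass
class NullModelFit:
    """Per-phenotype REML estimates; order matches the phenotype matrix."""

    sigma2_b: np.ndarray
    sigma2_e: np.ndarray
    alpha: list[np.ndarray]
    loglik: np.ndarray

    @property
    def q(self) -> int:
        return len(self.sigma2_b)

    def h2(self) -> np.ndarray:
        tot = self.sigma2_b + self.sigma2_e
        return self.sigma2_b / tot


def _restricted_negloglik(h, yt, Zt, d):
    """-2 * restricted log-likelihood (up to a constant) at ratio h."""
    lam = h * d + (1.0 - h)
    w = 1.0 / lam
    dof = len(yt) - Zt.shape[1]
    if Zt.shape[1] == 1:
        # intercept-only fast path (dominant case in replicate studies)
        z = Zt[:, 0]
        wz = w * z
        g = float(wz @ z)
        alpha = np.array([float(wz @ yt) / g])
        r = yt - alpha[0] * z
        rss = float(r @ (w * r))
        logdet_G = np.log(g)
    else:
        ZtW = Zt * w[:, None]
        G = ZtW.T @ Zt
        alpha = np.linalg.solve(G, ZtW.T @ yt)
        r = yt - Zt @ alpha
        rss = float(r @ (w * r))
        _, logdet_G = np.linalg.slogdet(G)
    if rss <= 0:
        return np.inf, alpha, np.nan
    neg2ll = dof * np.log(rss / dof) + float(np.log(lam).sum()) + logdet_G
    return neg2ll, alpha, rss / dof


def _profile_reml(yt: np.ndarray, Zt: np.ndarray, d: np.ndarray):
    """Profile REML over h in [0, 1). Returns (s2_b, s2_e, alpha, loglik)."""
    def objective(h):
        return _restricted_negloglik(h, yt, Zt, d)[0]

    grid = np.linspace(0.0, _H_MAX, 21)
    vals = [objective(h) for h in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": _H_TOL},
    )
    h = float(res.x)
    # snap to the boundary when it is at least as good
    for hb in (0.0, _H_MAX):
        if objective(hb) <= res.fun + 1e-10:
            h = hb
            break
    neg2ll, alpha, s2 = _restricted_negloglik(h, yt, Zt, d)
    return h * s2, (1.0 - h) * s2, alpha, -0.5 * neg2ll


def fit_null_reml(y: np.ndarray, Z, phi) -> tuple[float, float, np.ndarray, float]:
    """REML fit for one phenotype column with no missing values.

    Returns ``(sigma2_b, sigma2_e, alpha_hat, restricted_loglik)`` where the
    log-likelihood omits the usual additive constant.
    """
    ops = as_phi_ops(phi)
    Zv = Z.values if isinstance(Z, CovariateMatrix) else np.atleast_2d(Z)
    y = np.asarray(y, dtype=float)
    n, c = Zv.shape
    if len(y) != n or ops.n != n:
        raise DataError("y, Z and Phi must share the same number of rows")
    if n < c + 2:
        raise DegenerateModelError(f"need at least {c + 2} observations, got {n}")
    if np.ptp(y) == 0:
        raise DegenerateModelError("constant phenotype: variance is degenerate")
    yt = ops.to_eigenbasis(y)
    Zt = ops.to_eigenbasis(Zv)
    return _profile_reml(yt, Zt, ops.eigenvalues)


def fit_null_models(Y: PhenotypeMatrix, Z: CovariateMatrix, phi) -> NullModelFit:
    """Fit the univariate null REML for every phenotype column.

    Missing phenotype rows are dropped from the fit of that column only;
    the eigendecomposition of the corresponding Phi submatrix is cached per
    missingness pattern.
    """
    ops = as_phi_ops(phi)
    if Y.n != Z.n or Y.n != ops.n:
        raise DataError("phenotypes, covariates and Phi must be row-aligned")
    sub_cache: dict[bytes, PhiOps] = {}
    s2b = np.empty(Y.q)
    s2e = np.empty(Y.q)
    alphas: list[np.ndarray] = []
    logliks = np.empty(Y.q)
    for qi in range(Y.q):
        obs = ~np.isnan(Y.values[:, qi])
        if obs.all():
            sub = ops
            y, Zv = Y.values[:, qi], Z.values
        else:
            key = obs.tobytes()
            if key not in sub_cache:
                sub_cache[key] = PhiOps(ops.values[np.ix_(obs, obs)])
            sub = sub_cache[key]
            y, Zv = Y.values[obs, qi], Z.values[obs]
        s2b[qi], s2e[qi], alpha, logliks[qi] = fit_null_reml(y, Zv, sub)
        alphas.append(alpha)
    return NullModelFit(s2b, s2e, alphas, logliks)


def blup_offset(
    Y: PhenotypeMatrix, Z: CovariateMatrix, phi, fits: NullModelFit
) -> np.ndarray:
    """BLUP-adjusted phenotype matrix T.

    Column q is ``(I - Z (Z' H^-1 Z)^-1 Z' H^-1 - s2_B Phi P) y`` with
    ``H = s2_B Phi + s2_E I`` and ``P`` the REML projection, evaluated on the
    eigenbasis of Phi; algebraically this is ``(s2_E / lambda)`` times the
    GLS residual, coordinate-wise in the eigenbasis. Missing rows are zero.
    """
    ops = as_phi_ops(phi)
    if fits.q != Y.q:
        raise DataError("null-model fit does not match the phenotype matrix")
    if Y.n != Z.n or Y.n != ops.n:
        raise DataError("phenotypes, covariates and Phi must be row-aligned")
    T = np.zeros_like(Y.values)
    sub_cache: dict[bytes, PhiOps] = {}
    for qi in range(Y.q):
        obs = ~np.isnan(Y.values[:, qi])
        if obs.all():
            sub, y, Zv = ops, Y.values[:, qi], Z.values
        else:
            key = obs.tobytes()
            if key not in sub_cache:
                sub_cache[key] = PhiOps(ops.values[np.ix_(obs, obs)])
            sub = sub_cache[key]
            y, Zv = Y.values[obs, qi], Z.values[obs]
        s2b, s2e = fits.sigma2_b[qi], fits.sigma2_e[qi]
        lam = s2b * sub.eigenvalues + s2e
        yt = sub.to_eigenbasis(y)
        Zt = sub.to_eigenbasis(Zv)
        w = 1.0 / lam
        ZtW = Zt * w[:, None]
        alpha = np.linalg.solve(ZtW.T @ Zt, ZtW.T @ yt)
        resid_t = yt - Zt @ alpha
        T[obs, qi] = sub.from_eigenbasis((s2e * w) * resid_t)
    return zero_missing_phenotypes(T, Y.missing_mask)


def prevalence_offset(Y: PhenotypeMatrix, prevalence=None) -> np.ndarray:
    """Prevalence-adjusted T for dichotomous phenotypes: t = y - K_q."""
    K = prevalence if prevalence is not None else Y.prevalence
    if K is None:
        raise DataError("prevalence offset requires per-phenotype prevalence")
    K = np.asarray(K, dtype=float)
    if K.shape != (Y.q,):
        raise DataError("prevalence length must equal the number of phenotypes")
    if np.any((K <= 0) | (K >= 1)):
        raise DataError("prevalence must lie in (0, 1)")
    for qi, kind in enumerate(Y.kinds):
        if kind != DICHOTOMOUS:
            raise DataError(
                f"prevalence offset targets dichotomous phenotypes; "
                f"{Y.names[qi]!r} is {kind}"
            )
    return zero_missing_phenotypes(Y.values - K, Y.missing_mask)


def zero_missing_phenotypes(T: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Set entries flagged missing to exactly 0, leaving the rest unchanged."""
    T = np.array(T, dtype=float, copy=True)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != T.shape:
        raise DataError("missingness mask must match T")
    T[mask] = 0.0
    return T
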