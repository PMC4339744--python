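"""Multivariate quasi-likelihood score tests.

With ``A = Phi^-1 - Phi^-1 1 (1' Phi^-1 1)^-1 1' Phi^-1``, the score for
M markers and Q phenotypes is ``S = vec(T' Phi A X)`` and its variance is
``var(S) = Psi kron (T' Phi A Phi T)``; the statistic
``S' var(S)^-1 S`` is chi-square with M*Q degrees of freedom under the null.

Everything is evaluated through the identities ``Phi A X = X - 1 g'`` (BLUE
centering) and ``Phi A Phi = Phi - 1 (1' Phi^-1 1)^-1 1'``, so no N x N
projector is ever formed on the hot path. The vec ordering is marker-major:
entry ``m * Q + q`` is the score of phenotype q at marker m, matching the
Kronecker factor order ``Psi kron (.)``.

Variant configurations: MMQLS uses the prevalence offset with the same
score; MMASTOR uses the per-phenotype mixed-model covariance ``H^q`` as the
working variance, with covariance blocks
``Psi_mm' * (T^q)' (H^q)^-1 Phi A Phi (H^q')^-1 T^q'`` (derived by the same
covariance algebra; the multivariate V != I variance is an extension and is
flagged as such in the result metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from mfqls.exceptions import DataError, NoTestError
from mfqls.genotype_model import (
    GenotypeMatrix,
    blue_allele_freq,
    estimate_psi,
    polymorphic_mask,
)
from mfqls.linalg import as_phi_ops
from mfqls.null_model import (
    CovariateMatrix,
    NullModelFit,
    PhenotypeMatrix,
    blup_offset,
    fit_null_models,
    prevalence_offset,
)

__all__ = [
    "ScoreTestResult",
    "projection_A",
    "mfqls_score",
    "mfqls_variance",
    "mfqls_test",
    "mfqls_test_missing",
    "variant_test",
]

# relative eigenvalue cutoff for the pseudo-inverse of var(S)
RANK_TOL = 1e-8

METHODS = ("MFQLS", "MMQLS", "MMASTOR")


@dataclass
class ScoreTestResult:
    """Score test outcome for one variant set.

    ``score`` is the length-M*Q score vector in marker-major order and
    ``variance`` its M*Q x M*Q variance matrix. ``df`` is the retained rank
    of the variance (equal to M*Q unless the variance is rank-deficient).
    A no-test sentinel has ``df == 0`` and NaN statistic and p-value.
    """

    score: np.ndarray = field(repr=False)
    variance: np.ndarray = field(repr=False)
    statistic: float
    df: int
    p_value: float
    method: str = "MFQLS"
    n_used: int = 0
    markers: list[str] | None = None
    phenotypes: list[str] | None = None
    note: str = ""

    @classmethod
    def no_test(cls, method: str = "MFQLS", note: str = "", n_used: int = 0):
        return cls(
            score=np.zeros(0), variance=np.zeros((0, 0)),
            statistic=float("nan"), df=0, p_value=float("nan"),
            method=method, n_used=n_used, note=note or "no testable marker",
        )

    @property
    def is_no_test(self) -> bool:
        return self.df == 0


def projection_A(phi) -> np.ndarray:
    """Dense ``A = Phi^-1 - Phi^-1 1 (1' Phi^-1 1)^-1 1' Phi^-1``.

    Symmetric and annihilates constant vectors. Intended for small problems
    and cross-checks; the test routines never build it.
    """
    ops = as_phi_ops(phi)
    inv = ops.solve(np.eye(ops.n))
    w = ops.phi_inv_one
    return inv - ops.c * np.outer(w, w)


def _genotype_values(X) -> np.ndarray:
    values = X.values if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
    values = np.atleast_2d(values)
    if values.ndim != 2:
        raise DataError("genotypes must form an N x M matrix")
    return values


def _centered_genotypes(Xv: np.ndarray, ops) -> tuple[np.ndarray, np.ndarray]:
    """(Phi A X, BLUE mean genotype) without forming A."""
    ghat = ops.c * (ops.phi_inv_one @ Xv)
    return Xv - ghat, ghat


def mfqls_score(T: np.ndarray, phi, X) -> np.ndarray:
    """Score vector ``S = vec(T' Phi A X)`` in marker-major order."""
    ops = as_phi_ops(phi)
    Xv = _genotype_values(X)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[0] != ops.n or Xv.shape[0] != ops.n:
        raise DataError("T, Phi and X must be row-aligned")
    Xc, _ = _centered_genotypes(Xv, ops)
    return (T.T @ Xc).flatten(order="F")


def mfqls_variance(T: np.ndarray, phi, psi: np.ndarray) -> np.ndarray:
    """``var(S) = Psi kron (T' Phi A Phi T)`` in marker-major order."""
    ops = as_phi_ops(phi)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if T.shape[0] != ops.n:
        raise DataError("T and Phi must be row-aligned")
    # Phi A Phi = Phi - 1 (1' Phi^-1 1)^-1 1'
    col_sums = T.sum(axis=0)
    middle = T.T @ ops.mul(T) - ops.c * np.outer(col_sums, col_sums)
    return np.kron(psi, middle)


def _chi2_quadform(s: np.ndarray, V: np.ndarray) -> tuple[float, int, float]:
    """Statistic s' pinv(V) s with eigenvalue-thresholded pseudo-inverse.

    Degrees of freedom equal the retained rank; a rank-deficient variance
    with full-rank df would be anti-conservative.
    """
    eigval, eigvec = np.linalg.eigh((V + V.T) / 2.0)
    cutoff = RANK_TOL * max(eigval[-1], 0.0)
    keep = eigval > cutoff
    df = int(keep.sum())
    if df == 0:
        raise NoTestError("variance of the score is numerically zero")
    proj = eigvec[:, keep].T @ s
    stat = float(np.sum(proj**2 / eigval[keep]))
    return stat, df, float(chi2.sf(stat, df))


def _finalize(
    Smat: np.ndarray,
    middle: np.ndarray,
    psi: np.ndarray,
    method: str,
    n_used: int,
    markers,
    phenotypes,
    note: str = "",
) -> ScoreTestResult:
    s = Smat.flatten(order="F")
    V = np.kron(psi, middle)
    try:
        stat, df, p = _chi2_quadform(s, V)
    except NoTestError as exc:
        res = ScoreTestResult.no_test(method, str(exc), n_used)
        res.markers, res.phenotypes = markers, phenotypes
        return res
    return ScoreTestResult(
        score=s, variance=V, statistic=stat, df=df, p_value=p,
        method=method, n_used=n_used, markers=markers, phenotypes=phenotypes,
        note=note,
    )


def _marker_names(X, mask: np.ndarray) -> list[str]:
    if isinstance(X, GenotypeMatrix) and X.markers is not None:
        names = list(X.markers["snp"])
    else:
        names = [f"M{j + 1}" for j in range(len(mask))]
    return [nm for nm, keep in zip(names, mask) if keep]


def mfqls_test(
    T: np.ndarray, phi, X, psi: np.ndarray | None = None, method: str = "MFQLS"
) -> ScoreTestResult:
    """Joint score test of M markers against Q adjusted phenotypes.

    Monomorphic markers are dropped; if none remain, a no-test sentinel is
    returned. ``psi`` defaults to the sample covariance of the genotype rows.
    """
    ops = as_phi_ops(phi)
    Xv = _genotype_values(X)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[0] != ops.n or Xv.shape[0] != ops.n:
        raise DataError("T, Phi and X must be row-aligned")
    if np.isnan(Xv).any():
        raise DataError("mfqls_test requires complete genotypes; "
                        "use mfqls_test_missing")
    freq = blue_allele_freq(Xv, ops)
    poly = polymorphic_mask(freq)
    if not poly.any():
        return ScoreTestResult.no_test(method, "all markers monomorphic", ops.n)
    Xv = Xv[:, poly]
    if psi is None:
        psi = estimate_psi(Xv)
    else:
        psi = np.atleast_2d(np.asarray(psi, dtype=float))[np.ix_(poly, poly)]
    Xc, _ = _centered_genotypes(Xv, ops)
    Smat = T.T @ Xc
    col_sums = T.sum(axis=0)
    middle = T.T @ ops.mul(T) - ops.c * np.outer(col_sums, col_sums)
    return _finalize(
        Smat, middle, psi, method, ops.n,
        _marker_names(X, poly), _pheno_names(T),
    )


def _pheno_names(T: np.ndarray) -> list[str]:
    return [f"P{j + 1}" for j in range(T.shape[1])]


def mfqls_test_missing(
    T: np.ndarray, phi, X, psi: np.ndarray | None = None, method: str = "MFQLS"
) -> ScoreTestResult:
    """Score test keeping individuals with missing genotypes.

    With O the individuals with complete genotypes and U the rest, the score
    is ``S* = vec(T*' [Phi_OO; Phi_UO] A_OO X^O)`` and its variance
    ``Psi kron (T*' [Phi_OO; Phi_UO] A_OO [Phi_OO; Phi_UO]' T*)``, with
    ``A_OO`` the centering projector of ``Phi_OO``. When U is empty this is
    exactly the complete-data test. ``Psi`` is estimated from O only.
    """
    ops = as_phi_ops(phi)
    Xv = _genotype_values(X)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[0] != ops.n or Xv.shape[0] != ops.n:
        raise DataError("T, Phi and X must be row-aligned")
    obs = ~np.isnan(Xv).any(axis=1)
    if obs.all():
        return mfqls_test(T, ops, X, psi=psi, method=method)
    if not obs.any():
        return ScoreTestResult.no_test(method, "no individual has complete genotypes")
    X_O = Xv[obs]
    phi_full = ops.values
    phi_oo = phi_full[np.ix_(obs, obs)]
    chol = cho_factor(phi_oo, lower=True)
    w_o = cho_solve(chol, np.ones(int(obs.sum())))
    c_o = 1.0 / float(w_o.sum())
    ghat = c_o * (w_o @ X_O)
    freq = ghat / 2.0
    poly = polymorphic_mask(freq)
    if not poly.any():
        return ScoreTestResult.no_test(method, "all markers monomorphic", ops.n)
    X_O = X_O[:, poly]
    ghat = ghat[poly]
    if psi is None:
        psi = estimate_psi(X_O)
    else:
        psi = np.atleast_2d(np.asarray(psi, dtype=float))[np.ix_(poly, poly)]
    # R = [Phi_OO; Phi_UO]' T* = Phi[O, :] T   (N_O x Q)
    R = phi_full[obs, :] @ T
    solve_R = cho_solve(chol, R)
    Xc = X_O - ghat
    # R' A_OO X^O = R' Phi_OO^-1 (X^O - 1 g'): centering already in Xc
    Smat = solve_R.T @ Xc
    middle = R.T @ solve_R - c_o * np.outer(w_o @ R, w_o @ R)
    return _finalize(
        Smat, middle, psi, method, ops.n,
        _marker_names(X, poly), _pheno_names(T),
    )


def variant_test(
    method: str,
    Y: PhenotypeMatrix,
    Z: CovariateMatrix,
    phi,
    X,
    fits: NullModelFit | None = None,
    prevalence=None,
    psi: np.ndarray | None = None,
) -> ScoreTestResult:
    """High-level dispatch over the (V, mu) configurations.

    MFQLS — identity working variance, BLUP offset. MMQLS — identity
    working variance, prevalence offset (dichotomous phenotypes only).
    MMASTOR — per-phenotype mixed-model covariance H^q as the working
    variance, BLUP offset.
    """
    method = method.upper()
    if method not in METHODS:
        raise DataError(f"unknown method {method!r}; choose from {METHODS}")
    ops = as_phi_ops(phi)
    if method == "MMQLS":
        T = prevalence_offset(Y, prevalence)
        return _dispatch_complete_or_missing(T, ops, X, psi, method)
    if fits is None:
        fits = fit_null_models(Y, Z, ops)
    T = blup_offset(Y, Z, ops, fits)
    if method == "MFQLS":
        return _dispatch_complete_or_missing(T, ops, X, psi, method)
    return _mmastor_test(T, ops, X, fits, psi)


def _dispatch_complete_or_missing(T, ops, X, psi, method) -> ScoreTestResult:
    Xv = _genotype_values(X)
    if np.isnan(Xv).any():
        return mfqls_test_missing(T, ops, X, psi=psi, method=method)
    return mfqls_test(T, ops, X, psi=psi, method=method)


def _mmastor_test(
    T: np.ndarray, ops, X, fits: NullModelFit, psi: np.ndarray | None
) -> ScoreTestResult:
    """Generalized-V score with V^q = H^q = s2_B Phi + s2_E I per phenotype."""
    Xv = _genotype_values(X)
    if np.isnan(Xv).any():
        raise DataError("MMASTOR path requires complete genotypes")
    freq = blue_allele_freq(Xv, ops)
    poly = polymorphic_mask(freq)
    if not poly.any():
        return ScoreTestResult.no_test("MMASTOR", "all markers monomorphic", ops.n)
    Xv = Xv[:, poly]
    if psi is None:
        psi = estimate_psi(Xv)
    else:
        psi = np.atleast_2d(np.asarray(psi, dtype=float))[np.ix_(poly, poly)]
    Xc, _ = _centered_genotypes(Xv, ops)
    # U^q = (H^q)^-1 T^q, evaluated on the eigenbasis of Phi
    Tt = ops.to_eigenbasis(T)
    lam = (
        fits.sigma2_b[None, :] * ops.eigenvalues[:, None]
        + fits.sigma2_e[None, :]
    )
    Uq = ops.from_eigenbasis(Tt / lam)
    Smat = Uq.T @ Xc
    col_sums = Uq.sum(axis=0)
    middle = Uq.T @ ops.mul(Uq) - ops.c * np.outer(col_sums, col_sums)
    return _finalize(
        Smat, middle, psi, "MMASTOR", ops.n,
        _marker_names(X, poly), _pheno_names(T),
        note="multivariate V != I variance is an extension",
    )
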