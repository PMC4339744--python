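"""Genotype moments: BLUE allele frequencies, the marker covariance Psi,
and conditional expectations for missing genotypes.

The genotype vector of an individual across the M tested markers has
covariance ``Psi``; across individuals, ``var(vec(X)) = Psi kron Phi``. The
generalized-least-squares (BLUE) mean genotype under this structure is
``(1' Phi^-1 1)^-1 1' Phi^-1 X`` per marker, reported as an allele frequency
after halving. Because the test statistic only uses the genotype matrix
through a centering projector that annihilates constants, the allele-count
vs allele-frequency coding of the centering constant is immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from mfqls.exceptions import DataError
from mfqls.linalg import as_phi_ops

__all__ = [
    "GenotypeMatrix",
    "MarkerMoments",
    "blue_allele_freq",
    "estimate_psi",
    "conditional_expect_missing",
]

logger = logging.getLogger(__name__)


@dataclass
class GenotypeMatrix:
    """N x M minor-allele counts with NaN for missing calls."""

    values: np.ndarray = field(repr=False)
    markers: "object | None" = None  # pandas DataFrame (snp, chrom, pos, a1, a2)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        obs = self.values[~np.isnan(self.values)]
        if not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise DataError("genotype values must be in {0, 1, 2} or missing")
        if self.markers is not None:
            ids = list(self.markers["snp"])
            if len(ids) != len(set(ids)):
                raise DataError("marker ids must be unique")
            if len(ids) != self.m:
                raise DataError("marker metadata does not match genotype columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of individuals with no missing genotype."""
        return ~np.isnan(self.values).any(axis=1)


@dataclass
class MarkerMoments:
    """First and second moments of the tested markers.

    ``gamma`` — the slope of E(X | T) — is a nuisance that is never
    estimated: the test is a score test under H0: gamma = 0.
    """

    freq: np.ndarray
    psi: np.ndarray
    gamma: None = None


def blue_allele_freq(X, phi) -> np.ndarray:
    """Best linear unbiased allele-frequency estimates.

    Per marker, the BLUE of the mean genotype is
    ``g_m = (1' Phi^-1 1)^-1 1' Phi^-1 X^m``; the reported frequency is
    ``g_m / 2``. Rows must be complete (restrict or impute first).
    """
    ops = as_phi_ops(phi)
    values = X.values if isinstance(X, GenotypeMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    if values.shape[0] != ops.n:
        raise DataError("genotypes and Phi must be row-aligned")
    if np.isnan(values).any():
        raise DataError("blue_allele_freq requires complete genotype rows")
    g = ops.c * (ops.phi_inv_one @ values)
    return np.atleast_1d(g) / 2.0


def estimate_psi(X) -> np.ndarray:
    """Sample variance-covariance matrix of the per-individual genotype
    vectors (denominator N - 1), using individuals with complete genotypes."""
    values = X.values if isinstance(X, GenotypeMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    complete = ~np.isnan(values).any(axis=1)
    rows = values[complete]
    if rows.shape[0] < 2:
        raise DataError("Psi needs at least 2 individuals with complete genotypes")
    centered = rows - rows.mean(axis=0)
    return (centered.T @ centered) / (rows.shape[0] - 1)


def conditional_expect_missing(
    X_obs: np.ndarray,
    phi_oo: np.ndarray,
    phi_uo: np.ndarray,
    clip: bool = True,
) -> np.ndarray:
    """Expected genotypes of unobserved individuals given observed ones.

    Implements, per marker, the kinship-weighted conditional mean with the
    BLUE substituted for the allele frequency:

        E(X^U | X^O) = { 1_U b 1_O' inv(Phi_OO)
                         + Phi_UO (inv(Phi_OO) - inv(Phi_OO) 1 b 1' inv(Phi_OO)) } X^O

    with ``b = (1' inv(Phi_OO) 1)^-1``. Values are clipped to [0, 2]; no
    integer rounding is applied because the downstream score is linear in X.
    """
    X_obs = np.atleast_2d(np.asarray(X_obs, dtype=float))
    phi_oo = np.asarray(phi_oo, dtype=float)
    phi_uo = np.atleast_2d(np.asarray(phi_uo, dtype=float))
    n_o = X_obs.shape[0]
    if n_o == 0:
        raise DataError("no observed individuals to condition on")
    if phi_oo.shape != (n_o, n_o) or phi_uo.shape[1] != n_o:
        raise DataError("Phi partition does not match observed genotypes")
    if np.isnan(X_obs).any():
        raise DataError("observed genotype block must be complete")
    chol = cho_factor(phi_oo, lower=True)
    w = cho_solve(chol, np.ones(n_o))  # inv(Phi_OO) 1
    b = 1.0 / float(w.sum())
    ghat = b * (w @ X_obs)  # BLUE mean genotype per marker
    centered = cho_solve(chol, X_obs - ghat)  # inv(Phi_OO)(X^O - 1 ghat')
    out = ghat + phi_uo @ centered
    if clip:
        out = np.clip(out, 0.0, 2.0)
    return out


def polymorphic_mask(freq: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Markers whose estimated frequency is strictly inside (0, 1)."""
    freq = np.asarray(freq, dtype=float)
    mask = (freq > tol) & (freq < 1.0 - tol)
    if not mask.all():
        logger.warning(
            "dropping %d monomorphic marker(s) from the tested set",
            int((~mask).sum()),
        )
    return mask
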