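import numpy as np
import pytest
from scipy.stats import chi2, kstest

from mfqls.core import (
    ScoreTestResult,
    mfqls_score,
    mfqls_test,
    mfqls_test_missing,
    mfqls_variance,
    projection_A,
    variant_test,
)
from mfqls.genotype_model import estimate_psi
from mfqls.null_model import CovariateMatrix, NullModelFit, PhenotypeMatrix

from conftest import random_spd


# ---------------------------------------------------------------------------
# literal-formula oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def dense_A(phi):
    inv = np.linalg.inv(phi)
    w = inv @ np.ones(len(phi))
    return inv - np.outer(w, w) / w.sum()


def literal_score(T, phi, X):
    """Sum over individuals of kron(I_M, T_ij e_ij') vec(Phi A X)."""
    n, q = T.shape
    m = X.shape[1]
    vec_target = (phi @ dense_A(phi) @ X).flatten(order="F")  # length N*M
    S = np.zeros(m * q)
    for idx in range(n):
        e = np.zeros((n, 1))
        e[idx] = 1.0
        S += np.kron(np.eye(m), T[idx][:, None] @ e.T) @ vec_target
    return S


def literal_variance(T, phi, psi):
    """Double sum of kron(Psi, T_ij e_ij' Phi A Phi e_i'j' T_i'j'')."""
    n, q = T.shape
    m = psi.shape[0]
    A = dense_A(phi)
    mid_full = phi @ A @ phi
    V = np.zeros((m * q, m * q))
    for i in range(n):
        for j in range(n):
            V += np.kron(psi, np.outer(T[i], T[j]) * mid_full[i, j])
    return V


def make_instance(rng, n, m, q):
    phi = random_spd(rng, n)
    T = rng.standard_normal((n, q))
    X = rng.binomial(2, 0.4, size=(n, m)).astype(float)
    # guarantee polymorphism
    X[0] = 0.0
    X[1] = 2.0
    return T, phi, X


class TestProjectionA:
    def test_identity_phi(self):
        A = projection_A(np.eye(5))
        assert np.allclose(A, np.eye(5) - np.ones((5, 5)) / 5)

    def test_annihilates_constants(self, rng):
        phi = random_spd(rng, 9)
        A = projection_A(phi)
        assert np.max(np.abs(A @ np.ones(9))) < 1e-10
        assert np.allclose(A, A.T)

    def test_dense_formula_oracle(self, rng):
        phi = random_spd(rng, 5)
        assert np.allclose(projection_A(phi), dense_A(phi), atol=1e-10)


class TestScore:
    def test_zero_T(self, rng):
        T, phi, X = make_instance(rng, 8, 2, 2)
        assert np.allclose(mfqls_score(np.zeros_like(T), phi, X), 0.0)

    def test_constant_marker_annihilated(self, rng):
        T, phi, _ = make_instance(rng, 8, 1, 2)
        X = np.full((8, 1), 2.0)
        assert np.allclose(mfqls_score(T, phi, X), 0.0, atol=1e-10)

    def test_literal_oracle(self, rng):
        T, phi, X = make_instance(rng, 10, 2, 2)
        assert np.allclose(mfqls_score(T, phi, X), literal_score(T, phi, X),
                           atol=1e-8)

    def test_vec_ordering_marker_major(self, rng):
        T, phi, X = make_instance(rng, 10, 2, 3)
        S = mfqls_score(T, phi, X)
        Smat = T.T @ (phi @ dense_A(phi) @ X)  # Q x M
        assert np.allclose(S[:3], Smat[:, 0])
        assert np.allclose(S[3:], Smat[:, 1])


class TestVariance:
    def test_scalar_collapse(self, rng):
        T, phi, _ = make_instance(rng, 7, 1, 1)
        psi = np.array([[1.7]])
        V = mfqls_variance(T, phi, psi)
        A = dense_A(phi)
        expected = 1.7 * float(T[:, 0] @ phi @ A @ phi @ T[:, 0])
        assert V[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_zero_T(self, rng):
        _, phi, _ = make_instance(rng, 7, 1, 1)
        V = mfqls_variance(np.zeros((7, 2)), phi, np.eye(2))
        assert np.allclose(V, 0.0)

    def test_double_sum_oracle(self, rng):
        T, phi, X = make_instance(rng, 10, 2, 2)
        psi = estimate_psi(X)
        assert np.allclose(mfqls_variance(T, phi, psi),
                           literal_variance(T, phi, psi), atol=1e-8)


class TestMfqlsTest:
    def test_orthogonal_T_gives_zero(self, rng):
        n = 12
        X = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        X[0], X[1] = 0.0, 2.0
        Xc = X[:, 0] - X[:, 0].mean()
        # build T orthogonal to Xc and to the constant
        base = rng.standard_normal(n)
        t = base - base @ Xc / (Xc @ Xc) * Xc
        t -= t.mean()
        res = mfqls_test(t[:, None], np.eye(n), X)
        assert res.statistic == pytest.approx(0.0, abs=1e-16)
        assert res.p_value == pytest.approx(1.0)

    def test_invariant_to_marker_shift(self, rng):
        # the centering projector annihilates per-marker constants, so the
        # score (hence the statistic) ignores the centering convention
        T, phi, X = make_instance(rng, 10, 2, 2)
        s1 = mfqls_score(T, phi, X)
        s2 = mfqls_score(T, phi, X + np.array([5.0, -3.0]))
        assert np.allclose(s1, s2, atol=1e-10)

    def test_scalar_path_oracle(self, rng):
        n = 30
        X = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        X[0], X[1] = 0.0, 2.0
        t = rng.standard_normal(n)
        t -= t.mean()
        res = mfqls_test(t[:, None], np.eye(n), X)
        # independently coded scalar formula with Phi = I
        xc = X[:, 0] - X[:, 0].mean()
        psi = np.var(X[:, 0], ddof=1)
        stat = (t @ xc) ** 2 / (psi * (t @ t - t.sum() ** 2 / n))
        assert res.statistic == pytest.approx(stat, rel=1e-10)
        assert res.df == 1

    def test_rank_deficient_duplicate_markers(self, rng):
        n = 20
        x = rng.binomial(2, 0.4, size=n).astype(float)
        x[0], x[1] = 0.0, 2.0
        X = np.column_stack([x, x])
        t = rng.standard_normal((n, 1))
        res = mfqls_test(t, np.eye(n), X)
        assert res.df == 1  # rank-deficient var(S) -> reduced df
        assert np.isfinite(res.statistic)

    def test_all_monomorphic_sentinel(self, rng):
        t = rng.standard_normal((6, 1))
        res = mfqls_test(t, np.eye(6), np.zeros((6, 2)))
        assert res.is_no_test
        assert np.isnan(res.p_value)

    def test_permutation_equivariance(self, rng):
        T, phi, X = make_instance(rng, 12, 2, 2)
        psi = estimate_psi(X)
        r1 = mfqls_test(T, phi, X, psi=psi)
        perm = rng.permutation(12)
        r2 = mfqls_test(T[perm], phi[np.ix_(perm, perm)], X[perm], psi=psi)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed + 100)
        n = int(rng.integers(6, 13))
        m = int(rng.integers(1, 4))
        q = int(rng.integers(1, 4))
        T, phi, X = make_instance(rng, n, m, q)
        psi = estimate_psi(X)
        S = mfqls_score(T, phi, X)
        V = mfqls_variance(T, phi, psi)
        assert np.allclose(S, literal_score(T, phi, X), atol=1e-8)
        assert np.allclose(V, literal_variance(T, phi, psi), atol=1e-8)
        res = mfqls_test(T, phi, X, psi=psi)
        stat = S @ np.linalg.solve(V, S)
        assert res.statistic == pytest.approx(stat, rel=1e-6)


class TestMissingGenotypes:
    def test_reduction_when_complete(self, rng):
        T, phi, X = make_instance(rng, 10, 2, 2)
        psi = estimate_psi(X)
        r1 = mfqls_test(T, phi, X, psi=psi)
        r2 = mfqls_test_missing(T, phi, X, psi=psi)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
        assert r1.df == r2.df

    def test_zero_T_rows_equal_dropping(self, rng):
        T, phi, X = make_instance(rng, 10, 2, 2)
        Xm = X.copy()
        Xm[3, 0] = np.nan  # individual 3 unobserved
        Tz = T.copy()
        Tz[3] = 0.0
        psi = estimate_psi(X[np.arange(10) != 3])
        r_missing = mfqls_test_missing(Tz, phi, Xm, psi=psi)
        keep = np.arange(10) != 3
        r_drop = mfqls_test(
            Tz[keep], phi[np.ix_(keep, keep)], X[keep], psi=psi
        )
        assert r_missing.statistic == pytest.approx(r_drop.statistic, rel=1e-8)

    def test_literal_formula_oracle(self, rng):
        T, phi, X = make_instance(rng, 10, 2, 2)
        Xm = X.copy()
        Xm[7, :] = np.nan  # nonzero phenotype, missing genotypes
        obs = np.arange(10) != 7
        X_O = X[obs]
        psi = estimate_psi(X_O)
        res = mfqls_test_missing(T, phi, Xm, psi=psi)
        # brute-force displays: C = Phi[:, O], A_OO from Phi_OO
        phi_oo = phi[np.ix_(obs, obs)]
        A_oo = dense_A(phi_oo)
        C = phi[:, obs]
        inv = np.linalg.inv(phi_oo)
        w = inv @ np.ones(obs.sum())
        ghat = (w @ X_O) / w.sum()
        S = (T.T @ C @ A_oo @ X_O).flatten(order="F")
        V = np.kron(psi, T.T @ C @ A_oo @ C.T @ T)
        stat = S @ np.linalg.solve(V, S)
        assert np.allclose(res.score, S, atol=1e-8)
        assert np.allclose(res.variance, V, atol=1e-8)
        assert res.statistic == pytest.approx(stat, rel=1e-8)

    def test_downstream_reduction_via_imputation(self, rng):
        # with no missing individuals the imputation-based path is the
        # complete-data score exactly
        from mfqls.genotype_model import conditional_expect_missing

        T, phi, X = make_instance(rng, 10, 1, 1)
        imputed = conditional_expect_missing(X, phi, np.zeros((0, 10)))
        assert imputed.size == 0
        r1 = mfqls_test(T, phi, X)
        r2 = mfqls_test_missing(T, phi, X)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)


class TestVariantConfigurations:
    def _dich_dataset(self, rng, n=80):
        phi = np.eye(n)
        y = (rng.random((n, 2)) < 0.3).astype(float)
        Y = PhenotypeMatrix(y, kinds=["dichotomous"] * 2)
        Z = CovariateMatrix.intercept_only(n)
        X = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        X[0], X[1] = 0.0, 2.0
        return Y, Z, phi, X

    def test_mmqls_balanced(self, rng):
        Y, Z, phi, X = self._dich_dataset(rng)
        K = Y.values.mean(axis=0)
        res = variant_test("MMQLS", Y, Z, phi, X, prevalence=K)
        assert np.isfinite(res.statistic)
        assert res.method == "MMQLS"
        # T is exactly column-centered
        from mfqls.null_model import prevalence_offset

        T = prevalence_offset(Y, K)
        assert np.allclose(T.sum(axis=0), 0.0, atol=1e-10)

    def test_mmastor_equals_mfqls_when_s2b_zero(self, rng):
        n = 40
        phi = random_spd(rng, n)
        Y = PhenotypeMatrix(rng.standard_normal((n, 2)))
        Z = CovariateMatrix.intercept_only(n)
        X = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        X[0], X[1] = 0.0, 2.0
        fits = NullModelFit(
            np.zeros(2), np.array([1.4, 2.2]),
            [np.array([0.0]), np.array([0.0])], np.zeros(2),
        )
        r_mfqls = variant_test("MFQLS", Y, Z, phi, X, fits=fits)
        r_mmastor = variant_test("MMASTOR", Y, Z, phi, X, fits=fits)
        # H^q proportional to I: per-phenotype scalings cancel in the form
        assert r_mmastor.statistic == pytest.approx(r_mfqls.statistic, rel=1e-8)

    def test_unknown_method(self, rng):
        Y, Z, phi, X = self._dich_dataset(rng)
        from mfqls.exceptions import DataError

        with pytest.raises(DataError, match="unknown method"):
            variant_test("FOO", Y, Z, phi, X)


class TestNullCalibrationThreeMethods:
    def test_uniform_p_values(self):
        # common simulated null datasets; all three methods calibrated
        from mfqls.simulation import SimulationConfig, calibration_study

        cfg = SimulationConfig(n_families=60, q=2, dichotomous=True)
        res = calibration_study(
            cfg, 400, seed=202, methods=("MFQLS", "MMQLS", "MMASTOR")
        )
        for method in ("MFQLS", "MMQLS", "MMASTOR"):
            p = res.p_values[method].to_numpy()
            assert kstest(p, "uniform").pvalue > 0.01, method


class TestResultObject:
    def test_chi2_tail(self, rng):
        T, phi, X = make_instance(rng, 15, 1, 1)
        res = mfqls_test(T, phi, X)
        assert res.p_value == pytest.approx(chi2.sf(res.statistic, res.df))

    def test_no_test_sentinel_fields(self):
        res = ScoreTestResult.no_test("MFQLS", "nothing to test")
        assert res.is_no_test
        assert res.df == 0 and np.isnan(res.statistic)
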